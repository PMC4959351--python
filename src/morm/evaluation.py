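"""Evaluation harnesses for relatedness discovery.

Three study designs are supported:

1. *Differential-diagnosis recall* — for an anchor disease, candidates
   found through symptom-mediated paths (the interesting set F(steps)
   restricted to the disease ontology) are scored against a reference
   list of differential diagnoses, and compared with an intra-only
   baseline (the disease-ontology ball of the same radius).
2. *Disease-pair discovery* — F(steps) members are paired with the
   anchor and scored as a hit ratio against a confirmation list, with a
   seeded random-pairing baseline of the same size.
3. *Mask sweeps* — a family of link masks is applied to the network and
   the per-mask search-space statistics (edge counts, mean candidate
   counts, percentage of the unmasked count) are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .gim import AnchorSpec, ExpansionState
from .model import BMKN, BMKNError
from .pruning import MaskSet, apply_masks, interesting_set


@dataclass(frozen=True)
class ReferenceList:
    """An anchor concept and its externally confirmed partners."""

    anchor: str
    references: frozenset[str]

    def __post_init__(self) -> None:
        if self.anchor in self.references:
            raise BMKNError("anchor must not appear in its own reference set")


# ---------------------------------------------------------------------
# Design 1: differential-diagnosis recall
# ---------------------------------------------------------------------


def misdiagnosis_candidates(
    bmkn: BMKN, anchor: str, steps: int = 2, mask: Optional[MaskSet] = None
) -> frozenset[str]:
    """Diseases reachable from the anchor only via symptom-mediated
    (inter) paths: F(steps) restricted to the anchor's ontology."""
    spec = AnchorSpec(anchor, steps=steps, mask=mask)
    return interesting_set(bmkn, spec, steps, bmkn.ontology_of(anchor))


def intra_only_baseline(
    bmkn: BMKN, anchor: str, radius: int = 2, mask: Optional[MaskSet] = None
) -> frozenset[str]:
    """The intra-only ball: concepts within ``radius`` forward intra
    steps of the anchor in its own ontology (cell 0O^radius)."""
    spec = AnchorSpec(anchor, steps=radius, mask=mask)
    return ExpansionState(bmkn, spec).cell(0, radius, bmkn.ontology_of(anchor))


def recall_report(
    candidates: Iterable[str], reference: ReferenceList
) -> tuple[int, float]:
    """(matched count, percentage of the reference found)."""
    refs = reference.references
    if not refs:
        raise BMKNError("empty reference list")
    matched = len(set(candidates) & refs)
    return matched, 100.0 * matched / len(refs)


# ---------------------------------------------------------------------
# Design 2: disease pairs and hit ratios
# ---------------------------------------------------------------------


def disease_pair_candidates(
    bmkn: BMKN, anchor: str, steps: int = 2, mask: Optional[MaskSet] = None
) -> list[tuple[str, str]]:
    """One (anchor, partner) pair per member of the interesting set."""
    partners = misdiagnosis_candidates(bmkn, anchor, steps, mask)
    return [(anchor, p) for p in sorted(partners)]


def hit_ratio(
    pairs: Sequence[tuple[str, str]], confirmations: ReferenceList
) -> float:
    """Fraction of pairs whose partner appears in the confirmation list."""
    if not pairs:
        raise BMKNError("hit ratio undefined for zero pairs")
    hits = sum(partner in confirmations.references for _, partner in pairs)
    return hits / len(pairs)


def random_pair_baseline(
    universe: Iterable[str], anchor: str, n: int, seed: int
) -> list[tuple[str, str]]:
    """n distinct random partners from the universe (anchor excluded),
    sampled without replacement; deterministic per seed."""
    candidates = sorted(set(universe) - {anchor})
    if n > len(candidates):
        raise BMKNError(
            f"cannot sample {n} partners from a universe of {len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [(anchor, candidates[k]) for k in sorted(chosen)]


# ---------------------------------------------------------------------
# Aggregate reports
# ---------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-anchor and aggregate recall/hit-ratio comparison."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def mean_method_pct(self) -> float:
        return float(self.rows["method_pct"].mean())

    @property
    def mean_baseline_pct(self) -> float:
        return float(self.rows["baseline_pct"].mean())

    @property
    def mean_method_hit_ratio(self) -> float:
        return float(self.rows["method_hit_ratio"].mean())

    @property
    def mean_random_hit_ratio(self) -> float:
        return float(self.rows["random_hit_ratio"].mean())


def evaluate_anchors(
    bmkn: BMKN,
    references: Sequence[ReferenceList],
    steps: int = 2,
    seed: int = 0,
    mask: Optional[MaskSet] = None,
) -> EvalReport:
    """Run both comparative designs over a set of anchored references.

    Per anchor: N candidates from F(steps), their recall against the
    reference (method) next to the intra-only ball's recall (baseline),
    and the hit ratio of the N discovered pairs next to a same-size
    random pairing drawn from the anchor ontology (seeded).
    """
    if not references:
        raise BMKNError("no reference lists supplied")
    rows = []
    rng = np.random.default_rng(seed)
    for ref in references:
        candidates = misdiagnosis_candidates(bmkn, ref.anchor, steps, mask)
        baseline = intra_only_baseline(bmkn, ref.anchor, steps, mask)
        n1, pct1 = recall_report(candidates, ref)
        n2, pct2 = recall_report(baseline, ref)
        pairs = disease_pair_candidates(bmkn, ref.anchor, steps, mask)
        universe = bmkn.concept_ids(bmkn.ontology_of(ref.anchor))
        if pairs:
            method_hr = hit_ratio(pairs, ref)
            random_pairs = random_pair_baseline(
                universe, ref.anchor, len(pairs), int(rng.integers(0, 2**31))
            )
            random_hr = hit_ratio(random_pairs, ref)
        else:
            method_hr = 0.0
            random_hr = 0.0
        rows.append(
            {
                "anchor": ref.anchor,
                "n_reference": len(ref.references),
                "n_candidates": len(candidates),
                "method_matched": n1,
                "method_pct": round(pct1, 1),
                "baseline_matched": n2,
                "baseline_pct": round(pct2, 1),
                "method_hit_ratio": round(method_hr, 2),
                "random_hit_ratio": round(random_hr, 2),
            }
        )
    return EvalReport(rows=pd.DataFrame(rows))


# ---------------------------------------------------------------------
# Design 3: mask sweep
# ---------------------------------------------------------------------


def mask_sweep(
    bmkn: BMKN,
    mask_sets: Sequence[tuple[str, Optional[MaskSet]]],
    anchors: Sequence[str],
    steps: int = 2,
    target_ontology: Optional[str] = None,
) -> pd.DataFrame:
    """Search-space statistics per mask: edges kept, mean interesting-set
    size over the anchors, and percentage of the unmasked mean.

    ``mask_sets`` is a list of (label, MaskSet-or-None); None denotes
    the no-mask row, which defines the 100 % reference.  Candidates are
    counted in ``target_ontology`` (default: each anchor's own).
    """
    if not anchors:
        raise BMKNError("no anchors supplied")

    def _mean_count(mask: Optional[MaskSet]) -> float:
        total = 0
        for anchor in anchors:
            tgt = target_ontology or bmkn.ontology_of(anchor)
            spec = AnchorSpec(anchor, steps=steps, mask=mask)
            total += len(interesting_set(bmkn, spec, steps, tgt))
        return total / len(anchors)

    unmasked_mean = _mean_count(None)
    rows = []
    for label, mask in mask_sets:
        if mask is None:
            n_edges = bmkn.n_edges
            mean_count = unmasked_mean
        else:
            pruned, summary = apply_masks(bmkn, mask)
            n_edges = summary.n_kept
            mean_count = _mean_count(mask)
        pct = 100.0 * mean_count / unmasked_mean if unmasked_mean else 0.0
        rows.append(
            {
                "mask": label,
                "edges": n_edges,
                "mean_count": round(mean_count, 1),
                "mean_percentage": round(pct, 2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Reference-list files (TSV: anchor id <tab> reference id)
# ---------------------------------------------------------------------


def read_reference_lists(path) -> list[ReferenceList]:
    table = pd.read_csv(path, sep="\t", header=None, names=["anchor", "reference"])
    refs = []
    for anchor, group in table.groupby("anchor", sort=True):
        refs.append(ReferenceList(str(anchor), frozenset(group["reference"].astype(str))))
    return refs


def write_reference_lists(references: Sequence[ReferenceList], path) -> None:
    with open(path, "w") as handle:
        for ref in sorted(references, key=lambda r: r.anchor):
            for partner in sorted(ref.references):
                handle.write(f"{ref.anchor}\t{partner}\n")
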