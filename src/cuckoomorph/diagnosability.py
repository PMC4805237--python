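"""Pairwise subspecies diagnosability under the 75% rule.

For a continuous character (here usually the composite bill-size score) the
parametric diagnosability index for an ordered pair of populations
(focal i, reference j) is

    D_ij = |xbar_i - xbar_j| - t(p_i, n_i - 1) * s_i - t(p_j, n_j - 1) * s_j

with one-tailed Student-t quantiles, p_i = 0.75 (the focal population's
inner quantile) and p_j = 0.99 (the reference population's outer bound).
D >= 0 means at least 75% of the focal distribution lies beyond essentially
all of the reference distribution — the classical 75% rule for a valid
subspecies.  The index is asymmetric; a pair counts as diagnosable only when
both ordered directions pass (reciprocal diagnosability).

For ordinal characters (ventral color scores) the rule is applied directly
to the observed distributions: the focal fraction strictly outside the
reference's observed range, compared with 3/4 in exact rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

#: Quantile levels of the classical 75% rule.
P_FOCAL_DEFAULT = 0.75
P_REFERENCE_DEFAULT = 0.99


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one taxon for the parametric index."""

    label: str
    n: int
    mean: float
    sd: float  # sample sd, divisor n-1

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2 (t undefined)")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


def summarize_groups(values: Sequence[float], labels: Sequence[str]) -> list[GroupSummary]:
    """Per-label (n, mean, sd) summaries in first-appearance order."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "label": list(labels)})
    order = df["label"].drop_duplicates().tolist()
    out = []
    for lab in order:
        v = df.loc[df["label"] == lab, "value"].to_numpy()
        out.append(GroupSummary(lab, len(v), float(v.mean()), float(v.std(ddof=1))))
    return out


def d_index(
    focal: GroupSummary,
    reference: GroupSummary,
    p_focal: float = P_FOCAL_DEFAULT,
    p_reference: float = P_REFERENCE_DEFAULT,
) -> float:
    """Diagnosability of ``focal`` from ``reference`` (asymmetric).

    Swapping the arguments swaps which standard deviation receives which
    quantile multiplier.  A zero sd simply drops that term, so point-mass
    groups reduce to the distance between means.
    """
    for p, name in ((p_focal, "p_focal"), (p_reference, "p_reference")):
        if not 0.5 < p < 1.0:
            raise ValueError(f"{name} must lie in (0.5, 1), got {p}")
    gap = abs(focal.mean - reference.mean)
    return float(
        gap
        - t_dist.ppf(p_focal, focal.n - 1) * focal.sd
        - t_dist.ppf(p_reference, reference.n - 1) * reference.sd
    )


@dataclass(frozen=True)
class DiagnosabilityMatrix:
    """All ordered-pair indices plus the diagnosis decisions.

    ``d`` holds D[i, j] with row i focal and column j reference (diagonal
    NaN); ``diagnosable`` applies the threshold (D >= 0 by default) per
    direction; ``reciprocal`` is the symmetric AND of both directions.
    """

    taxa: tuple[str, ...]
    d: pd.DataFrame
    diagnosable: pd.DataFrame
    reciprocal: pd.DataFrame
    threshold: float = 0.0

    def formatted(self, decimals: int = 2) -> pd.DataFrame:
        """Display layout: 2-decimal strings, diagnosable cells starred."""
        out = self.d.round(decimals).astype(object)
        for i in self.taxa:
            for j in self.taxa:
                if i == j:
                    out.loc[i, j] = "-"
                else:
                    mark = "*" if self.diagnosable.loc[i, j] else ""
                    out.loc[i, j] = f"{self.d.loc[i, j]:.{decimals}f}{mark}"
        return out


def d_matrix(
    groups: Sequence[GroupSummary],
    p_focal: float = P_FOCAL_DEFAULT,
    p_reference: float = P_REFERENCE_DEFAULT,
    threshold: float = 0.0,
) -> DiagnosabilityMatrix:
    """Parametric index for every ordered pair of groups.

    Group order is preserved in the output.  D >= threshold flags a
    direction as diagnosable; the reciprocal matrix is symmetric by
    construction.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate taxon labels in {labels}")
    n = len(groups)
    D = np.full((n, n), np.nan)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if i != j:
                D[i, j] = d_index(gi, gj, p_focal, p_reference)
    d = pd.DataFrame(D, index=labels, columns=labels)
    diag = d >= threshold
    for lab in labels:
        diag.loc[lab, lab] = False
    recip = diag & diag.T
    return DiagnosabilityMatrix(
        taxa=tuple(labels), d=d, diagnosable=diag, reciprocal=recip, threshold=threshold
    )


def empirical_75(
    focal_scores: Sequence[float], reference_scores: Sequence[float]
) -> dict:
    """Range-based 75% rule for ordinal scores.

    Fraction of focal scores strictly outside [min(reference),
    max(reference)], in exact rational arithmetic; diagnosable iff the
    fraction is >= 3/4.  Asymmetric: a narrow reference range is easy to
    fall outside of, a wide one is not.
    """
    focal = list(focal_scores)
    reference = list(reference_scores)
    if not focal or not reference:
        raise ValueError("score lists must be non-empty")
    lo, hi = min(reference), max(reference)
    outside = sum(1 for x in focal if x < lo or x > hi)
    frac = Fraction(outside, len(focal))
    return {
        "fraction_outside": frac,
        "fraction": float(frac),
        "n_outside": outside,
        "n_focal": len(focal),
        "diagnosable": frac >= Fraction(3, 4),
    }


def empirical_matrix(
    values: Sequence[float], labels: Sequence[str]
) -> DiagnosabilityMatrix:
    """Range-rule fractions for every ordered pair of labelled score sets.

    The ``d`` field holds the outside fractions; a direction is diagnosable
    at fraction >= 0.75.
    """
    df = pd.DataFrame({"value": list(values), "label": list(labels)})
    order = df["label"].drop_duplicates().tolist()
    if len(order) < 2:
        raise ValueError("need >= 2 groups")
    F = pd.DataFrame(np.nan, index=order, columns=order)
    diag = pd.DataFrame(False, index=order, columns=order)
    by = {lab: df.loc[df["label"] == lab, "value"].tolist() for lab in order}
    for i in order:
        for j in order:
            if i == j:
                continue
            res = empirical_75(by[i], by[j])
            F.loc[i, j] = res["fraction"]
            diag.loc[i, j] = res["diagnosable"]
    recip = diag & diag.T
    return DiagnosabilityMatrix(
        taxa=tuple(order), d=F, diagnosable=diag, reciprocal=recip, threshold=0.75
    )


def reciprocal_report(matrix: DiagnosabilityMatrix) -> dict:
    """Who is reciprocally diagnosable from whom, and is anyone from all?

    Returns per-taxon partner lists, the taxa (if any) reciprocally
    diagnosable from every other taxon, and the global verdict.
    """
    per_taxon = {
        t: [u for u in matrix.taxa if u != t and bool(matrix.reciprocal.loc[t, u])]
        for t in matrix.taxa
    }
    fully = [t for t, partners in per_taxon.items() if len(partners) == len(matrix.taxa) - 1]
    return {
        "per_taxon": per_taxon,
        "fully_diagnosable_taxa": fully,
        "any_fully_diagnosable": bool(fully),
        "n_reciprocal_pairs": int(matrix.reciprocal.to_numpy().sum() // 2),
    }
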