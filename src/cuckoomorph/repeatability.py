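"""Measurement repeatability (intraclass correlation) from one-way ANOVA.

With specimens as the grouping factor and measurement sessions as
replicates, the one-way ANOVA mean squares give the among-specimen variance
component s2_A = (MS_among - MS_within) / n0 and the repeatability

    r = s2_A / (s2_A + MS_within),

where n0 = (N - sum(n_i^2)/N) / (a - 1) for a specimens and N total
measurements (n0 equals the session count k in a balanced design).  r may be
negative when MS_among <= MS_within; it is returned unclamped with a flag.
Ordinal color scores are treated as numeric in the same decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED = ("specimen_id", "trait", "session", "value")


@dataclass(frozen=True)
class RepeatabilityResult:
    trait: str
    r: float
    ms_among: float
    ms_within: float
    n0: float
    var_among: float
    var_within: float
    n_specimens: int
    n_measurements: int
    flags: tuple[str, ...] = ()


class RepeatSet:
    """Paired (or multi-) session measurements in long format.

    Wraps a table with columns (specimen_id, trait, session, value); every
    specimen must have at least two sessions for each trait it appears under.
    """

    def __init__(self, sessions: pd.DataFrame):
        missing = [c for c in REQUIRED if c not in sessions.columns]
        if missing:
            raise ValueError(f"repeat table missing column(s): {missing}")
        df = sessions.dropna(subset=["value"]).copy()
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"]).all():
            raise ValueError("non-finite measurement values")
        self.sessions = df

    @property
    def traits(self) -> list[str]:
        return sorted(self.sessions["trait"].unique())

    def groups(self, trait: str) -> list[np.ndarray]:
        """Per-specimen session values for one trait, in specimen-id order."""
        sub = self.sessions[self.sessions["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no measurements for trait {trait!r}")
        return [g.to_numpy() for _, g in sub.groupby("specimen_id")["value"]]


def repeatability(repeat_set: RepeatSet, trait: str) -> RepeatabilityResult:
    """ANOVA-based repeatability of one trait.

    Raises ``ValueError`` when fewer than two specimens are present or any
    specimen has a single session.  Zero total variance (all measurements
    identical) defines r = 1 with a ``degenerate`` flag.
    """
    groups = repeat_set.groups(trait)
    a = len(groups)
    if a < 2:
        raise ValueError(f"need >= 2 specimens for {trait!r}, got {a}")
    sizes = np.array([len(g) for g in groups])
    if (sizes < 2).any():
        bad = int((sizes < 2).sum())
        raise ValueError(f"{bad} specimen(s) with a single session for {trait!r}")
    n_total = int(sizes.sum())
    values = np.concatenate(groups)
    grand = values.mean()

    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_among = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(sizes, groups)))
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_total - a)
    n0 = (n_total - (sizes**2).sum() / n_total) / (a - 1)

    flags: list[str] = []
    if ss_among + ss_within == 0.0:
        return RepeatabilityResult(
            trait, 1.0, 0.0, 0.0, float(n0), 0.0, 0.0, a, n_total, ("degenerate",)
        )
    var_among = (ms_among - ms_within) / n0
    r = var_among / (var_among + ms_within)
    if r < 0:
        flags.append("negative_repeatability")
    return RepeatabilityResult(
        trait=trait,
        r=float(r),
        ms_among=float(ms_among),
        ms_within=float(ms_within),
        n0=float(n0),
        var_among=float(var_among),
        var_within=float(ms_within),
        n_specimens=a,
        n_measurements=n_total,
        flags=tuple(flags),
    )


def repeat_differences(repeat_set: RepeatSet, trait: str) -> dict[str, float]:
    """Absolute between-session differences for one trait.

    For two-session specimens this is the |first - second| difference; with
    extra sessions, all within-specimen pairwise differences contribute.
    Returns the maximum and mean absolute difference in trait units.
    """
    diffs: list[float] = []
    for g in repeat_set.groups(trait):
        if len(g) < 2:
            raise ValueError(f"specimen with a single session for {trait!r}")
        i, j = np.triu_indices(len(g), k=1)
        diffs.extend(np.abs(g[i] - g[j]))
    arr = np.asarray(diffs)
    return {"max_abs_diff": float(arr.max()), "mean_abs_diff": float(arr.mean())}


def summarize(repeat_set: RepeatSet) -> pd.DataFrame:
    """Repeatability and repeat-difference summary for every trait present."""
    rows = []
    for trait in repeat_set.traits:
        res = repeatability(repeat_set, trait)
        d = repeat_differences(repeat_set, trait)
        rows.append(
            {
                "trait": trait,
                "r": res.r,
                "ms_among": res.ms_among,
                "ms_within": res.ms_within,
                "n0": res.n0,
                "n_specimens": res.n_specimens,
                "max_abs_diff": d["max_abs_diff"],
                "mean_abs_diff": d["mean_abs_diff"],
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows).set_index("trait")
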