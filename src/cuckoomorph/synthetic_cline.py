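"""Synthetic specimen tables with known clinal structure.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage has ground truth:

* a multivariate bill-size cline across an ordered island arc, with a steep
  logistic step between the Greater and Lesser Antilles and phenotypically
  intermediate populations on Antigua/Barbuda and on the mainland;
* four ordinal ventral color scores produced by thresholding correlated
  latent Gaussians, with a unimodal darkness profile peaking at Dominica;
* duplicate measurement sessions with configurable session noise, implying a
  known target repeatability r* = s2_between / (s2_between + error_sd^2);
* sex labels drawn independently of phenotype.

Randomness flows through one integer seed; each stage draws from a derived
substream so stages can be re-run independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .specimen_data import (
    BILL_TRAITS,
    COLOR_TRAITS,
    COLUMNS,
    SPECIMEN_COUNTS,
    TAXON_REGION_MAP,
)

#: One sampling locale per subspecies, in geographic order (Florida, then
#: clockwise around the Caribbean).  ``position`` is the coordinate fed to the
#: cline function (0 = small-billed extreme, 1 = large-billed extreme);
#: ``darkness`` is the latent color mean (0 = palest), peaking at Dominica.
_LOCALE_SPECS = (
    # name,            subspecies,      position, darkness
    ("florida_bahamas", "maynardi",      0.00, 0.2),
    ("cayman_islands",  "caymanensis",   0.05, 0.4),
    ("greater_antilles_w", "nesiotes",   0.08, 1.6),
    ("greater_antilles_e", "teres",      0.12, 1.4),
    ("antigua_barbuda", "rileyi",        0.50, 1.8),
    ("dominica",        "dominicae",     0.95, 2.6),
    ("st_vincent",      "vincentis",     1.00, 2.0),
    ("grenada",         "grenadensis",   0.92, 0.6),
    ("south_america",   "minor",         0.50, 0.8),
    ("middle_america_car", "continentalis", 0.52, 1.6),
    ("providencia",     "abbotti",       0.48, 1.5),
    ("middle_america_pac", "palloris",   0.45, 0.7),
)


@dataclass(frozen=True)
class Locale:
    """One collection locale: labels plus its coordinates on the two clines."""

    name: str
    subspecies: str
    region: str
    position: float     # bill-size cline coordinate in [0, 1]
    darkness: float     # latent color mean (latent-Gaussian units)
    n: int              # specimens to draw


@dataclass(frozen=True)
class ClineConfig:
    """Full description of a synthetic world.

    Bill means at a locale are ``baseline + amplitude * g(position)`` where
    ``g`` is the cline function selected by ``cline_shape``:

    * ``logistic_step`` — 1/(1+exp(-steepness*(x-center))): a step between the
      Greater and Lesser Antilles with intermediates at half height;
    * ``linear`` — g(x) = x;
    * ``flat`` — g(x) = 0 everywhere (the null world).

    Trait units are mm; ``within_locale_cov`` is the common 3x3 covariance of
    (length, width, depth) within a locale.  Color scores arise from four
    correlated latent Gaussians (pairwise correlation ``color_corr``) with
    per-region offsets, cut at ``color_thresholds`` into ordinals 0..len(thr).
    ``repeat_error_sd`` is the between-session measurement noise per trait.
    """

    locales: tuple[Locale, ...]
    bill_baseline: tuple[float, float, float] = (19.0, 6.0, 7.0)
    bill_amplitude: tuple[float, float, float] = (3.1, 1.55, 1.35)
    cline_shape: str = "logistic_step"
    cline_center: float = 0.5
    cline_steepness: float = 12.0
    within_locale_cov: tuple[tuple[float, ...], ...] = ()
    color_thresholds: tuple[float, ...] = (-1.0, 0.0, 1.0, 2.0, 3.0)
    color_corr: float = 0.7
    color_region_offsets: tuple[float, float, float, float] = (-0.3, 0.0, 0.15, 0.3)
    repeat_error_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "bill_length_mm": 0.12,
            "bill_width_mm": 0.27,
            "bill_depth_mm": 0.08,
            "color_chin": 0.3,
            "color_breast": 0.3,
            "color_belly": 0.3,
            "color_vent": 0.3,
        }
    )
    sex_ratio: float = 0.5
    prop_sex_unknown: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.within_locale_cov:
            object.__setattr__(self, "within_locale_cov", _default_cov())
        validate_config(self)

    @property
    def cov(self) -> np.ndarray:
        return np.asarray(self.within_locale_cov, dtype=float)

    def bill_means(self) -> pd.DataFrame:
        """Per-locale true mean vectors (rows = locales, cols = bill traits)."""
        g = _cline_function(self.cline_shape, self.cline_center, self.cline_steepness)
        rows = {
            loc.name: np.asarray(self.bill_baseline) + np.asarray(self.bill_amplitude) * g(loc.position)
            for loc in self.locales
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(BILL_TRAITS))


def _default_cov(sds=(0.9, 0.45, 0.40), rho=0.5) -> tuple[tuple[float, ...], ...]:
    s = np.asarray(sds)
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    return tuple(map(tuple, corr * np.outer(s, s)))


def _cline_function(shape: str, center: float, steepness: float):
    if shape == "logistic_step":
        return lambda x: 1.0 / (1.0 + np.exp(-steepness * (x - center)))
    if shape == "linear":
        return lambda x: float(x)
    if shape == "flat":
        return lambda x: 0.0
    raise ValueError(f"unknown cline_shape {shape!r}")


def validate_config(config: ClineConfig) -> None:
    cov = config.cov
    if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
        raise ValueError("within_locale_cov must be a symmetric 3x3 matrix")
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("within_locale_cov must be positive-definite")
    thr = np.asarray(config.color_thresholds)
    if not np.all(np.diff(thr) > 0):
        raise ValueError("color_thresholds must be strictly increasing")
    if any(loc.n < 1 for loc in config.locales):
        raise ValueError("per-locale counts must be >= 1")
    if not 0.0 <= config.sex_ratio <= 1.0:
        raise ValueError("sex_ratio must lie in [0, 1]")
    if not -1.0 / 3.0 < config.color_corr < 1.0:
        raise ValueError("color_corr must give a positive-definite latent correlation")


def _default_locales(n_per_subspecies: Mapping[str, int] | None = None) -> tuple[Locale, ...]:
    counts = dict(SPECIMEN_COUNTS)
    if n_per_subspecies:
        counts.update(n_per_subspecies)
    return tuple(
        Locale(name, ssp, TAXON_REGION_MAP[ssp], pos, dark, counts[ssp])
        for name, ssp, pos, dark in _LOCALE_SPECS
    )


def build_config(
    preset: str = "paper_like",
    *,
    seed: int = 0,
    n_per_subspecies: Mapping[str, int] | None = None,
    **overrides,
) -> ClineConfig:
    """Build a :class:`ClineConfig` from a named preset.

    Presets
    -------
    ``paper_like``
        Logistic step cline centered between the Greater and Lesser Antilles,
        intermediates on Antigua/Barbuda and the mainland, color darkness
        peaking at Dominica, sample sizes of the museum series (274 total).
    ``flat_null``
        Identical bill means and color darkness at every locale.
    ``two_cluster``
        Two well-separated mean vectors (extremes of the step only, no
        intermediate locales).

    Keyword overrides are applied on top of the preset; invalid overrides
    (e.g. a non-positive-definite covariance) raise ``ValueError``.
    """
    locales = _default_locales(n_per_subspecies)
    if preset == "paper_like":
        cfg = ClineConfig(locales=locales, seed=seed)
    elif preset == "flat_null":
        flat = tuple(replace(loc, darkness=1.5) for loc in locales)
        cfg = ClineConfig(locales=flat, cline_shape="flat", seed=seed)
    elif preset == "two_cluster":
        extremes = tuple(
            replace(loc, position=round(loc.position))
            for loc in locales
            if loc.position <= 0.12 or loc.position >= 0.92
        )
        cfg = ClineConfig(
            locales=extremes, cline_shape="logistic_step", cline_steepness=200.0, seed=seed
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


_STAGE_SPECIMENS = 1
_STAGE_REPEATS = 2


def _rng(config: ClineConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def sample_specimens(config: ClineConfig) -> pd.DataFrame:
    """Draw a specimen table from the configured world.

    Deterministic under a fixed seed.  Bill triples come from the locale's
    multivariate normal; the recorded values are the specimens' true values
    rounded to 0.1 mm (session noise enters only through
    :func:`sample_repeats`).  The unrounded truth is kept in ``_true_*``
    columns for downstream calibration checks.
    """
    rng = _rng(config, _STAGE_SPECIMENS)
    means = config.bill_means()
    cov = config.cov
    n_colors = len(COLOR_TRAITS)
    latent_corr = np.full((n_colors, n_colors), config.color_corr)
    np.fill_diagonal(latent_corr, 1.0)
    thr = np.asarray(config.color_thresholds)
    offsets = np.asarray(config.color_region_offsets)

    frames = []
    counter = 0
    for loc in config.locales:
        bills = rng.multivariate_normal(means.loc[loc.name].to_numpy(), cov, size=loc.n)
        latent = rng.multivariate_normal(
            loc.darkness + offsets, latent_corr, size=loc.n
        )
        scores = np.searchsorted(thr, latent)  # ordinal 0..len(thr)
        u = rng.random(loc.n)
        sex = np.where(
            u < config.prop_sex_unknown,
            "unknown",
            np.where(rng.random(loc.n) < config.sex_ratio, "female", "male"),
        )
        years = rng.integers(1877, 1987, size=loc.n)
        months = rng.integers(1, 13, size=loc.n)
        ids = [f"SYN-{counter + i:04d}" for i in range(loc.n)]
        counter += loc.n
        df = pd.DataFrame(
            {
                "specimen_id": ids,
                "repository": "synthetic",
                "subspecies": loc.subspecies,
                "region": loc.region,
                "locale": loc.name,
                "sex": sex,
                "collection_date": pd.to_datetime(
                    {"year": years, "month": months, "day": 15}
                ),
            }
        )
        for j, trait in enumerate(BILL_TRAITS):
            df[trait] = np.round(bills[:, j], 1)
            df[f"_true_{trait}"] = bills[:, j]
        for j, trait in enumerate(COLOR_TRAITS):
            df[trait] = scores[:, j].astype(float)
        df["flags"] = ""
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return table[[*COLUMNS, *(f"_true_{t}" for t in BILL_TRAITS)]]


@dataclass(frozen=True)
class RepeatDraw:
    """Duplicate measurement sessions plus the repeatability they imply.

    ``sessions`` is a long-format table (specimen_id, trait, session, value);
    ``expected_r`` maps each trait to r* = s2_between / (s2_between + sd^2)
    computed from the sampled specimens' true values.
    """

    sessions: pd.DataFrame
    expected_r: dict[str, float]


def expected_repeatability(sigma_between: float, error_sd: float) -> float:
    """r* for given between-specimen sd and within-session error sd."""
    v = float(sigma_between) ** 2
    return v / (v + float(error_sd) ** 2)


def sample_repeats(
    table: pd.DataFrame,
    k: int,
    config: ClineConfig,
    traits: Sequence[str] = BILL_TRAITS + COLOR_TRAITS,
    n_sessions: int = 2,
) -> RepeatDraw:
    """Re-measure ``k`` randomly chosen specimens in ``n_sessions`` sessions.

    Each session value is the specimen's true value plus independent
    N(0, repeat_error_sd) noise, rounded to 0.1 mm for bill traits and
    re-discretized (rounded, clipped to the ordinal range) for color scores.
    With ``repeat_error_sd = 0`` the sessions are identical.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    rng = _rng(config, _STAGE_REPEATS)
    idx = rng.choice(len(table), size=k, replace=False)
    chosen = table.iloc[np.sort(idx)]
    n_levels = len(config.color_thresholds)

    rows = []
    expected = {}
    for trait in traits:
        sd = float(config.repeat_error_sd.get(trait, 0.0))
        truth_col = f"_true_{trait}" if f"_true_{trait}" in chosen.columns else trait
        truth = chosen[truth_col].to_numpy(dtype=float)
        expected[trait] = expected_repeatability(np.std(truth, ddof=1), sd)
        for s in range(1, n_sessions + 1):
            vals = truth + rng.normal(0.0, sd, size=k) if sd > 0 else truth.copy()
            if trait in COLOR_TRAITS:
                vals = np.clip(np.round(vals), 0, n_levels)
            else:
                vals = np.round(vals, 1)
            rows.append(
                pd.DataFrame(
                    {
                        "specimen_id": chosen["specimen_id"].to_numpy(),
                        "trait": trait,
                        "session": s,
                        "value": vals,
                    }
                )
            )
    sessions = pd.concat(rows, ignore_index=True).sort_values(
        ["trait", "specimen_id", "session"], kind="stable", ignore_index=True
    )
    return RepeatDraw(sessions=sessions, expected_r=expected)
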