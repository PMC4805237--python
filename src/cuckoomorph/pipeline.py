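"""End-to-end orchestration: load or simulate, QC, analyze, report.

``run_pipeline`` sequences the stages in their natural order — specimen
counts, repeatability, sex MANOVA screen, PCA composite bill size,
clustering with optimal-k, discriminant analysis per grouping level, and
75%-rule diagnosability matrices (parametric on PC1, empirical range rule on
breast color) — and writes every artifact as CSV/JSON together with the
fully serialized configuration, so re-running a config byte-reproduces the
bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnosability as dx
from . import multivariate as mv
from . import repeatability as rp
from . import specimen_data as sd
from . import synthetic_cline as sc

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialized into the output bundle."""

    input_csv: str | None = None          # path to a conforming specimen CSV …
    preset: str | None = "paper_like"     # … or a synthetic preset
    output_dir: str = "cuckoomorph_out"
    seed: int = 0
    color_range: tuple[int, int] = sd.DEFAULT_COLOR_RANGE
    grouping_levels: tuple[str, ...] = ("region", "subspecies")
    p_focal: float = dx.P_FOCAL_DEFAULT
    p_reference: float = dx.P_REFERENCE_DEFAULT
    d_threshold: float = 0.0
    k_range: tuple[int, int] = (2, 10)
    n_repeats: int = 17                   # specimens re-measured (synthetic runs)
    manova_alpha: float = 0.05            # sexes pooled when screen is above this
    force_pool_sexes: bool = False
    color_trait_for_rule: str = "color_breast"

    def __post_init__(self):
        if self.input_csv is None and self.preset is None:
            raise ValueError("either input_csv or preset is required")
        if not self.k_range[0] >= 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range must be (lo>=2, hi>=lo)")


def tabulate_collections(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subspecies specimen counts and collection-month ranges.

    Month ranges are reported where dates exist and marked unknown
    otherwise; an empty input yields an empty table with a warning.
    """
    if table.empty:
        logger.warning("tabulate_collections: empty input")
        return pd.DataFrame(columns=["n", "first_month", "last_month"])
    rows = {}
    for ssp, grp in table.groupby("subspecies", sort=True):
        dates = pd.to_datetime(grp["collection_date"], errors="coerce").dropna()
        rows[ssp] = {
            "n": len(grp),
            "first_month": int(dates.dt.month.min()) if len(dates) else "unknown",
            "last_month": int(dates.dt.month.max()) if len(dates) else "unknown",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _load(config: PipelineConfig) -> tuple[pd.DataFrame, sc.RepeatDraw | None]:
    if config.input_csv is not None:
        table = sd.read_specimens(config.input_csv, color_range=config.color_range)
        return table, None
    cfg = sc.build_config(config.preset, seed=config.seed)
    table = sc.sample_specimens(cfg)
    repeats = sc.sample_repeats(table, k=min(config.n_repeats, len(table)), config=cfg)
    return table, repeats


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns it as a dict.

    Stage failures propagate as exceptions carrying the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": dataclasses.asdict(config)}

    table, repeats = _run_stage("load", _load, config)
    results["n_specimens"] = len(table)
    sd.write_specimens(table.drop(columns=[c for c in table.columns if c.startswith("_true_")]),
                       out / "specimens.csv")

    counts = _run_stage("tabulate", tabulate_collections, table)
    counts.to_csv(out / "collection_counts.csv")
    results["counts_per_subspecies"] = counts["n"].to_dict() if "n" in counts else {}

    if repeats is not None:
        rs = rp.RepeatSet(repeats.sessions)
        summary = _run_stage("repeatability", rp.summarize, rs)
        summary.to_csv(out / "repeatability.csv")
        results["repeatability"] = summary["r"].to_dict()
        results["expected_repeatability"] = repeats.expected_r

    bills, qc_report = sd.complete_cases(table, list(sd.BILL_TRAITS))
    results["qc"] = {"bill_complete": qc_report["n_kept"], "dropped": len(qc_report["dropped"])}

    # sex screen: pool sexes downstream unless the MANOVA rejects
    manova = _run_stage(
        "manova", mv.pillai_manova, bills, sd.BILL_TRAITS, "sex", "subspecies"
    )
    results["sex_manova"] = {k: manova[k] for k in ("pillai", "approx_F", "p")}
    pooled = config.force_pool_sexes or manova["p"] > config.manova_alpha
    results["sexes_pooled"] = bool(pooled)
    if not pooled:
        logger.warning("sex screen significant (p=%.3g); analyses still pool sexes "
                       "but the flag is recorded", manova["p"])

    pca = _run_stage("pca", mv.pca_composite, bills, sd.BILL_TRAITS)
    results["pc1_variance_share"] = float(pca.variance_ratio[0])
    results["pc1_trait_correlations"] = pca.loading_correlations.round(4).to_dict()
    pca.scores.to_csv(out / "pca_scores.csv", index=False)

    screen = _run_stage("mahalanobis", mv.mahalanobis_screen, bills, sd.BILL_TRAITS)
    screen.to_csv(out / "mahalanobis_screen.csv", index=False)

    dend = _run_stage("cluster", mv.cluster_complete, bills, sd.BILL_TRAITS)
    kres = _run_stage(
        "optimal_k", mv.optimal_k, dend, bills, sd.BILL_TRAITS,
        range(config.k_range[0], config.k_range[1] + 1),
    )
    results["optimal_k"] = kres["k_best"]
    results["k_votes"] = kres["votes"]
    labels = dend.cut(kres["k_best"])
    cluster_counts = (
        pd.crosstab(bills["region"], pd.Series(labels, index=bills.index, name="cluster"))
        .reindex(list(sd.REGIONS), fill_value=0)
    )
    cluster_counts.to_csv(out / "cluster_counts_by_region.csv")
    results["cluster_counts_by_region"] = {
        r: row.to_dict() for r, row in cluster_counts.iterrows()
    }

    results["lda"] = {}
    for level in config.grouping_levels:
        lda = _run_stage("lda", mv.lda_fit, bills, sd.BILL_TRAITS, level)
        lda.confusion.round(2).to_csv(out / f"lda_confusion_{level}.csv")
        correct = float(np.mean(lda.predictions.to_numpy() == bills[level].to_numpy()))
        results["lda"][level] = {
            "axis1_between_group_share": float(lda.between_group_ratio[0]),
            "overall_correct": correct,
            "axis1_coefficients": lda.coefficients.iloc[:, 0].round(4).to_dict(),
        }

    # diagnosability on the composite bill-size score
    pc1 = pca.pc1
    results["diagnosability"] = {}
    for level in config.grouping_levels:
        order = (
            list(sd.REGIONS)
            if level == "region"
            else [s for s in sd.SUBSPECIES if s in set(bills[level])]
        )
        frame = pd.DataFrame({"score": pc1.to_numpy(), "label": bills[level].to_numpy()})
        frame["label"] = pd.Categorical(frame["label"], categories=order, ordered=True)
        frame = frame.sort_values("label", kind="stable")
        groups = dx.summarize_groups(frame["score"], frame["label"].astype(str))
        mat = _run_stage(
            "diagnosability", dx.d_matrix, groups,
            config.p_focal, config.p_reference, config.d_threshold,
        )
        mat.formatted().to_csv(out / f"diagnosability_{level}.csv")
        rep = dx.reciprocal_report(mat)
        results["diagnosability"][level] = {
            "any_fully_diagnosable": rep["any_fully_diagnosable"],
            "n_reciprocal_pairs": rep["n_reciprocal_pairs"],
            "per_taxon": rep["per_taxon"],
        }

    # empirical range rule on the chosen color trait, by subspecies
    color_tbl, _ = sd.complete_cases(table, [config.color_trait_for_rule])
    if len(color_tbl) and color_tbl["subspecies"].nunique() >= 2:
        emat = dx.empirical_matrix(
            color_tbl[config.color_trait_for_rule], color_tbl["subspecies"]
        )
        emat.d.round(3).to_csv(out / "color_rule_fractions.csv")
        erep = dx.reciprocal_report(emat)
        results["color_rule"] = {
            "any_fully_diagnosable": erep["any_fully_diagnosable"],
            "n_reciprocal_pairs": erep["n_reciprocal_pairs"],
        }
        colors, _ = sd.complete_cases(table, list(sd.COLOR_TRAITS))
        if len(colors) >= 3:
            rho = mv.rank_correlations(colors, sd.COLOR_TRAITS)
            rho.round(3).to_csv(out / "color_rank_correlations.csv")
            off = rho.to_numpy()[np.triu_indices(len(sd.COLOR_TRAITS), k=1)]
            results["color_spearman_range"] = [float(np.nanmin(off)), float(np.nanmax(off))]

    with open(out / "report.json", "w") as fh:
        json.dump(results, fh, indent=2, default=_json_default)
    logger.info("pipeline bundle written to %s", out)
    return results


def _run_stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
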