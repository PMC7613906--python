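"""Full study replica: simulate -> preprocess -> discover -> validate -> report.

Orchestrates the complete analysis over a synthetic (or user-supplied)
cohort: PCA metabotype discovery with covariate overlay, three pairwise
OPLS-DA comparisons validated by ensemble external CV with permutation-null
KS significance, VIP-based bin selection with fold changes and univariate
confirmation, PANSS clinical comparisons, and an antibody-blind
high-vs-low-PANSS contrast model.  The report is a plain dict (written as
JSON plus a human-readable summary) and is byte-identical for identical
configurations.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemometrics import detect_spontaneous_clusters, fit_pca, overlay_covariates
from .preprocessing import (
    BinnedMatrix,
    ColumnScaler,
    PreprocessConfig,
    assemble_matrix,
    normalize_and_scale,
)
from .synthetic import CohortConfig, EffectConfig, generate_cohort
from .univariate import bonferroni_adjust, compare_groups, fold_changes
from .validation import ModelConfig, validate_comparison

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]

DEFAULT_COMPARISONS = (
    ("NMDAR_LGI1_CASPR2", "Control"),
    ("VGKC_GlyR", "Control"),
    ("VGKC_GlyR", "NMDAR_LGI1_CASPR2"),
)

PANSS_SCALES = ("panss_total", "panss_positive", "panss_negative", "panss_general")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_repetitions: int = 50
    n_permutations: int = 100
    alpha: float = 0.05
    pca_components: int = 2
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS

    def __post_init__(self) -> None:
        # one master seed; every stochastic stage derives an explicit offset
        self.cohort = replace(self.cohort, seed=self.seed)


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML mapping (missing keys default)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_raw = raw.get("cohort", {})
    effects_raw = cohort_raw.pop("effects", None)
    effects = EffectConfig(**effects_raw) if effects_raw else EffectConfig()
    if cohort_raw.get("group_sizes"):
        cohort_raw["group_sizes"] = dict(cohort_raw["group_sizes"])
    cohort = CohortConfig(effects=effects, **cohort_raw)
    pp = PreprocessConfig(**raw.get("preprocess", {}))
    model = ModelConfig(**raw.get("model", {}))
    comps = tuple(tuple(c) for c in raw.get("comparisons", DEFAULT_COMPARISONS))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        cohort=cohort,
        preprocess=pp,
        model=model,
        n_repetitions=int(raw.get("n_repetitions", 50)),
        n_permutations=int(raw.get("n_permutations", 100)),
        alpha=float(raw.get("alpha", 0.05)),
        pca_components=int(raw.get("pca_components", 2)),
        comparisons=comps,
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort naming the stage
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: RunConfig):
    return generate_cohort(config.cohort)


@_stage("preprocess")
def _preprocess(spectra, meta, config: RunConfig) -> BinnedMatrix:
    bm = assemble_matrix(spectra, meta, config.preprocess)
    return normalize_and_scale(bm, config.preprocess.normalization, "none", center=False)


@_stage("pca_discovery")
def _pca_discovery(bm: BinnedMatrix, meta: pd.DataFrame, config: RunConfig) -> dict:
    scaler = ColumnScaler(config.preprocess.scaling, config.preprocess.center)
    X = scaler.fit(bm.values.to_numpy(float)).transform(bm.values.to_numpy(float))
    pca = fit_pca(pd.DataFrame(X, index=bm.values.index, columns=bm.values.columns),
                  config.pca_components)
    labels, silhouette = detect_spontaneous_clusters(pca.scores, 2, seed=config.seed)
    meta_rows = meta.set_index("sample_id").loc[bm.sample_ids]
    overlay = overlay_covariates(labels, meta_rows.reset_index())
    sizes = np.bincount(labels, minlength=2)
    # which analysis groups populate the minority cluster?
    minority = int(np.argmin(sizes))
    minority_groups = (
        meta_rows.loc[np.asarray(labels) == minority, "analysis_group"].value_counts().to_dict()
    )
    return {
        "pca": pca,
        "labels": labels,
        "cluster_sizes": sorted(int(s) for s in sizes),
        "silhouette": float(silhouette),
        "minority_cluster_groups": {str(k): int(v) for k, v in minority_groups.items()},
        "explained_variance_fraction": [float(v) for v in pca.explained_variance_fraction],
        "covariate_overlay": overlay,
    }


@_stage("univariate_confirmation")
def _confirm_bins(bm: BinnedMatrix, groups: pd.Series, selected: list[str]) -> pd.DataFrame:
    """One-way ANOVA/Tukey per selected bin across the three analysis groups."""
    rows = []
    for b in selected:
        res = compare_groups(bm.values[b].to_numpy(), groups.to_numpy(),
                             method="anova_tukey", variable=b)
        row = {"bin": b, "omnibus_p": res.omnibus_p}
        for _, pr in res.posthoc.iterrows():
            row[f"tukey_p_{pr['group1']}_vs_{pr['group2']}"] = pr["p_raw"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["omnibus_p_bonferroni"] = bonferroni_adjust(
            out["omnibus_p"].to_numpy(), m=len(out)
        )
    return out


@_stage("clinical_panss")
def _clinical(meta: pd.DataFrame, alpha: float) -> dict:
    out = {}
    for scale in PANSS_SCALES:
        res = compare_groups(
            meta[scale].to_numpy(), meta["analysis_group"].to_numpy(),
            method="kruskal_dunn", alpha=alpha, variable=scale,
        )
        out[scale] = {
            "medians": {
                g: float(meta.loc[meta["analysis_group"] == g, scale].median())
                for g in sorted(meta["analysis_group"].unique())
            },
            "kruskal_p": res.omnibus_p,
            "dunn": [
                {
                    "pair": f"{r['group1']} vs {r['group2']}",
                    "p_adjusted": float(r["p_adjusted"]),
                }
                for _, r in res.posthoc.iterrows()
            ],
        }
    return out


def run_pipeline(config: RunConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Execute every stage and return the report dict.

    When ``outdir`` is given, per-stage artifacts (matrix, metrics, null
    distributions, VIP curves, selected bins, statistics tables) and the
    report (JSON + text) are written as they are produced, so a failing
    stage leaves earlier artifacts on disk.
    """
    config = config if config is not None else RunConfig()
    out = Path(outdir) if outdir is not None else None
    logger = logging.getLogger("psymetab.pipeline")
    handler = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    t_start = time.perf_counter()
    logger.info("pipeline start: seed=%d, sizes=%s", config.seed, dict(config.cohort.group_sizes))

    spectra, meta, truth = _simulate(config)
    logger.info("simulate: %d spectra (%.1fs)", len(spectra), time.perf_counter() - t_start)
    t_pp = time.perf_counter()
    bm = _preprocess(spectra, meta, config)
    logger.info(
        "preprocess: %dx%d matrix, normalization=%s (%.1fs)",
        *bm.values.shape, config.preprocess.normalization, time.perf_counter() - t_pp,
    )
    meta_used = meta.set_index("sample_id").loc[bm.sample_ids].reset_index()
    if out is not None:
        bm.values.to_csv(out / "matrix.csv")
        meta.to_csv(out / "metadata.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    disc = _pca_discovery(bm, meta, config)
    logger.info(
        "pca_discovery: cluster sizes %s, silhouette %.2f",
        disc["cluster_sizes"], disc["silhouette"],
    )
    if out is not None:
        pcs = [f"PC{i+1}" for i in range(disc["pca"].scores.shape[1])]
        pd.DataFrame(disc["pca"].scores, index=bm.sample_ids, columns=pcs).assign(
            cluster=disc["labels"]
        ).to_csv(out / "pca_scores.csv")
        pd.DataFrame(disc["pca"].loadings, index=bm.bin_labels, columns=pcs).to_csv(
            out / "pca_loadings.csv"
        )
        disc["covariate_overlay"].to_csv(out / "covariate_overlay.csv", index=False)

    groups = meta_used.set_index("sample_id")["analysis_group"]
    report_comparisons = {}
    for i, (case, ref) in enumerate(config.comparisons):
        name = f"{case}_vs_{ref}"
        try:
            mask = groups.isin([case, ref])
            X = bm.values.loc[mask[mask].index]
            y = groups[mask].to_numpy()
            res = validate_comparison(
                X, y, case, config.model,
                n_repetitions=config.n_repetitions,
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                seed=config.seed + 100 * (i + 1),
            )
            folds = fold_changes(bm.values, groups, res.selected_bins, reference=ref)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            logger.error("comparison %s failed: %s", name, exc)
            raise PipelineError(f"comparison_{name}", exc) from exc
        confirm = _confirm_bins(bm, groups, res.selected_bins)
        logger.info(
            "comparison %s: accuracy %.3f (null %.3f), %d bins selected (seed %d)",
            name,
            res.metrics["accuracy"].mean(),
            res.null_metrics["accuracy"].mean(),
            len(res.selected_bins),
            config.seed + 100 * (i + 1),
        )
        if out is not None:
            cdir = out / name
            cdir.mkdir(exist_ok=True)
            res.metrics.to_csv(cdir / "metrics.csv", index=False)
            res.null_metrics.to_csv(cdir / "null_metrics.csv", index=False)
            (cdir / "ks.json").write_text(json.dumps(res.ks, indent=2, sort_keys=True))
            res.mean_vip.loc[res.vip_order].to_csv(cdir / "vip_curve.csv")
            folds.loc[res.selected_bins].to_csv(cdir / "selected_bins.csv")
            confirm.to_csv(cdir / "stats.tsv", sep="\t", index=False)
        report_comparisons[name] = {
            "case": case,
            "reference": ref,
            "metrics": {
                m: {
                    "mean": float(res.metrics[m].mean()),
                    "sd": float(res.metrics[m].std(ddof=1)),
                    "null_mean": float(res.null_metrics[m].mean()),
                    "ks_p": res.ks[m]["p"],
                    "significant": res.ks[m]["significant"],
                }
                for m in res.metrics.columns
            },
            "n_selected_bins": len(res.selected_bins),
            "selected_bins": res.selected_bins,
            "vip_cutoff": res.vip_cutoff,
            "n_confirmed_bins": int((confirm["omnibus_p_bonferroni"] <= config.alpha).sum())
            if len(confirm)
            else 0,
        }

    clinical = _clinical(meta_used, config.alpha)

    # antibody-blind severity contrast: high vs low PANSS at the cohort median
    median_total = float(meta_used["panss_total"].median())
    severity = np.where(meta_used["panss_total"] >= median_total, "high", "low")
    try:
        res_sev = validate_comparison(
            bm.values.loc[meta_used["sample_id"]],
            severity,
            "high",
            config.model,
            n_repetitions=config.n_repetitions,
            n_permutations=max(20, config.n_permutations // 5),
            alpha=config.alpha,
            seed=config.seed + 100 * (len(config.comparisons) + 1),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("high_vs_low_panss", exc) from exc
    anchor = "VGKC_GlyR_vs_Control"
    severity_report = {
        "split_median": median_total,
        "n_high": int(np.sum(severity == "high")),
        "n_low": int(np.sum(severity == "low")),
        "metrics": {
            m: {"mean": float(res_sev.metrics[m].mean()), "sd": float(res_sev.metrics[m].std(ddof=1))}
            for m in res_sev.metrics.columns
        },
    }
    if anchor in report_comparisons:
        severity_report["accuracy_vs_antibody_model_pct"] = 100.0 * (
            res_sev.metrics["accuracy"].mean()
            - report_comparisons[anchor]["metrics"]["accuracy"]["mean"]
        )

    report = {
        "config": {
            "seed": config.seed,
            "group_sizes": dict(config.cohort.group_sizes),
            "normalization": config.preprocess.normalization,
            "scaling": config.preprocess.scaling,
            "center": config.preprocess.center,
            "n_orth": config.model.n_orth,
            "n_folds": config.model.n_folds,
            "n_repetitions": config.n_repetitions,
            "n_permutations": config.n_permutations,
            "alpha": config.alpha,
            "knee_method": "max-chord-distance with VIP>1 fallback",
            "comparisons": [list(c) for c in config.comparisons],
        },
        "cohort": {
            "n_samples": int(len(meta)),
            "n_used": int(len(meta_used)),
            "excluded_multi_positive": bm.provenance.get("excluded_multi_positive", []),
            "n_bins": int(bm.values.shape[1]),
        },
        "pca_discovery": {
            k: disc[k]
            for k in (
                "cluster_sizes",
                "silhouette",
                "minority_cluster_groups",
                "explained_variance_fraction",
            )
        },
        "covariate_overlay": disc["covariate_overlay"].drop(columns=["note"]).to_dict("records"),
        "comparisons": report_comparisons,
        "panss": clinical,
        "high_vs_low_panss": severity_report,
        "truth": {"planted_bins": truth.get("planted_bins", [])},
    }
    logger.info("pipeline done (%.1fs total)", time.perf_counter() - t_start)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "report.txt").write_text(_render_report(report))
    if handler is not None:
        logger.removeHandler(handler)
        handler.close()
    return report


def _render_report(report: dict) -> str:
    lines = ["Serum NMR metabotyping pipeline report", "=" * 40, ""]
    c = report["cohort"]
    lines.append(
        f"Cohort: {c['n_samples']} samples ({c['n_used']} used, "
        f"{len(c['excluded_multi_positive'])} excluded multi-positive), {c['n_bins']} bins"
    )
    p = report["pca_discovery"]
    lines.append(
        f"PCA discovery: cluster sizes {p['cluster_sizes']}, silhouette {p['silhouette']:.2f}, "
        f"minority cluster groups {p['minority_cluster_groups']}"
    )
    lines.append("")
    for name, comp in report["comparisons"].items():
        lines.append(f"Comparison {name}:")
        for m, v in comp["metrics"].items():
            star = " *" if v["significant"] else ""
            lines.append(
                f"  {m:12s} {100*v['mean']:6.2f} +/- {100*v['sd']:.2f}%  "
                f"(null {100*v['null_mean']:.1f}%, KS p={v['ks_p']:.3g}){star}"
            )
        lines.append(
            f"  selected bins: {comp['n_selected_bins']} (VIP cutoff {comp['vip_cutoff']:.2f}); "
            f"{comp['n_confirmed_bins']} confirmed (ANOVA/Tukey, Bonferroni)"
        )
    lines.append("")
    lines.append("PANSS comparisons (Kruskal-Wallis + Dunn):")
    for scale, v in report["panss"].items():
        med = ", ".join(f"{g}={x:.0f}" for g, x in v["medians"].items())
        lines.append(f"  {scale}: medians {med}; Kruskal p={v['kruskal_p']:.3g}")
    s = report["high_vs_low_panss"]
    lines.append("")
    lines.append(
        f"High-vs-low PANSS model (split at median {s['split_median']:.0f}): "
        f"accuracy {100*s['metrics']['accuracy']['mean']:.2f}%"
        + (
            f" ({s['accuracy_vs_antibody_model_pct']:+.2f} percentage points vs antibody model)"
            if "accuracy_vs_antibody_model_pct" in s
            else ""
        )
    )
    return "\n".join(lines) + "\n"
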