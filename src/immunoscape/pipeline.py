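"""End-to-end orchestration: config in, artifact files + summary JSON out.

Stages run in a fixed order (I/O or simulation -> ssGSEA -> composite scores
-> clustering/splits -> contrasts -> survival); every stage writes its table
so each step can be re-run from disk, and the JSON summary is deterministic
for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import data_io, phenotype, scores, simulate, ssgsea, stats, survival

log = logging.getLogger("immunoscape")

SUMMARY_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """Wraps a failure with the stage name and offending entity."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "immunoscape_run"
    inputs: Mapping[str, str] | None = None  # expression / gmt / clinical paths
    simulate: Mapping[str, Any] | None = None  # GeneratorConfig overrides
    ssgsea: Mapping[str, Any] = field(default_factory=dict)
    scores: Mapping[str, Any] = field(default_factory=dict)
    clustering: Mapping[str, Any] = field(default_factory=dict)
    contrasts: list[Mapping[str, Any]] = field(default_factory=list)
    survival_strata: list[Mapping[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config must name exactly one of 'inputs' or 'simulate'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _default_contrasts(cell_types: list[str]) -> list[dict[str, Any]]:
    base = [
        {"score": name, "group_by": "side", "test": "mann_whitney"}
        for name in ("cyt", "tis", "apm", "ifng", "cd8_treg_ratio", "overall_infiltration")
    ]
    if "CD56bright NK cells" in cell_types:
        base.append(
            {"score": "CD56bright NK cells", "group_by": "side", "test": "mann_whitney"}
        )
    return base


def _default_strata() -> list[dict[str, Any]]:
    return [
        {"score": "CD56bright NK cells", "within_side": "left"},
        {"score": "p41bb", "within_side": "left"},
        {"score": "ifna", "within_side": "left"},
        {
            "score": "CD56bright NK cells",
            "cross_with": "p41bb",
            "within_side": "left",
        },
    ]


def run_all(cfg: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns the summary dict (also written as JSON)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }

    def _stage(name):
        t0 = time.perf_counter()

        def done(**info):
            elapsed = time.perf_counter() - t0
            log.info("stage %s done in %.2fs: %s", name, elapsed, info)
            summary["stages"][name] = info

        return done

    collected: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- stage: inputs -------------------------------------------------
        done = _stage("inputs")
        try:
            if cfg.simulate is not None:
                gen_cfg = simulate.GeneratorConfig(seed=cfg.seed, **dict(cfg.simulate))
                expr, clinical, sets, truth = simulate.generate(gen_cfg)
                data_io.write_expression(expr, outdir / "expression.tsv")
                data_io.write_gmt(sets, outdir / "sets.gmt")
                data_io.write_clinical(clinical, outdir / "clinical.tsv")
                simulate.truth_report(truth, outdir)
                cell_types = list(gen_cfg.cell_types)
            else:
                expr = data_io.read_expression(cfg.inputs["expression"])
                sets = data_io.read_gmt(cfg.inputs["gmt"])
                clinical = data_io.read_clinical(cfg.inputs["clinical"])
                cell_types = list(cfg.scores.get("cell_types") or sets.names)
            expr, clinical = data_io.intersect_samples(expr, clinical)
        except Exception as exc:
            raise StageError("inputs", exc) from exc
        done(n_genes=expr.shape[0], n_samples=expr.shape[1], n_sets=len(sets.names))

        # ---- stage: ssgsea -------------------------------------------------
        done = _stage("ssgsea")
        try:
            ss_cfg = ssgsea.SsgseaConfig(**dict(cfg.ssgsea))
            enrich = ssgsea.score_matrix(expr, sets, ss_cfg)
            ssgsea.write_enrichment(enrich, outdir / "enrichment.tsv")
        except Exception as exc:
            raise StageError("ssgsea", exc) from exc
        done(alpha=ss_cfg.alpha, normalized=ss_cfg.normalize, n_sets=len(enrich.set_names))

        # ---- stage: composite_scores ---------------------------------------
        done = _stage("composite_scores")
        try:
            score_kwargs = {
                k: v
                for k, v in dict(cfg.scores).items()
                if k
                in {
                    "tis_set_names",
                    "cd8_name",
                    "treg_name",
                    "pathway_names",
                    "ifng_mode",
                    "pseudocount",
                    "delta",
                }
            }
            table, meta = scores.build_composite_table(
                expr, enrich, sets, cell_types, cfg=ss_cfg, **score_kwargs
            )
            scores.write_scores(table, meta, outdir / "scores.tsv")
        except Exception as exc:
            raise StageError("composite_scores", exc) from exc
        done(columns=list(table.columns))

        # ---- stage: immunophenotype ----------------------------------------
        done = _stage("immunophenotype")
        try:
            cell_enrich = ssgsea.EnrichmentMatrix(
                enrich.scores.loc[cell_types],
                normalized=enrich.normalized,
                alpha=enrich.alpha,
                tie_policy=enrich.tie_policy,
            )
            clusters = phenotype.cluster_infiltration(
                cell_enrich, distance=cfg.clustering.get("distance", "euclidean")
            )
            classes = pd.DataFrame({"cluster": clusters.labels})
            strata_cfg = list(cfg.survival_strata) or _default_strata()
            split_cols: dict[str, pd.Series] = {}
            for spec_item in strata_cfg:
                name = spec_item["score"]
                series = _resolve_score(name, table, enrich)
                split = phenotype.median_split(series, name=f"{name}_split")
                split_cols[name] = split
                classes[f"{name}_split"] = split
                if spec_item.get("cross_with"):
                    other_name = spec_item["cross_with"]
                    other = split_cols.get(other_name)
                    if other is None:
                        other = phenotype.median_split(
                            _resolve_score(other_name, table, enrich),
                            name=f"{other_name}_split",
                        )
                    classes[f"{name}_x_{other_name}"] = phenotype.cross_classes(
                        split, other
                    )
            phenotype.write_classes(classes, outdir / "classes.tsv")
        except Exception as exc:
            raise StageError("immunophenotype", exc) from exc
        done(cluster_sizes=clusters.sizes, distance=clusters.distance)
        summary["cluster_sizes"] = clusters.sizes

        # ---- stage: cohort_stats -------------------------------------------
        done = _stage("cohort_stats")
        try:
            side = clinical.table["side"]
            contrasts = list(cfg.contrasts) or _default_contrasts(cell_types)
            results: dict[str, stats.ComparisonResult] = {}
            for c in contrasts:
                series = _resolve_score(c["score"], table, enrich)
                if c.get("group_by", "side") == "side":
                    labels = side[side.isin(["left", "right"])]
                elif c["group_by"] == "cluster":
                    labels = clusters.labels
                else:
                    labels = clinical.table[c["group_by"]]
                key = f"{c['score']}|{c.get('group_by', 'side')}|{c.get('test', 'mann_whitney')}"
                test = c.get("test", "mann_whitney")
                if test == "anova":
                    results[key] = stats.anova_oneway(series, labels)
                else:
                    results[key] = stats.compare_groups(series, labels, test=test)
            frame = stats.comparisons_to_frame(results)
            frame.to_csv(outdir / "stats.tsv", sep="\t")
            # VEGFA coupling, per side, when VEGFA is measured
            correlations: dict[str, dict[str, float]] = {}
            if "VEGFA" in expr.values.index:
                vegfa = expr.values.loc["VEGFA"]
                cd8_row = cfg.scores.get("cd8_name", "CD8 T cells")
                target = (
                    enrich.scores.loc[cd8_row]
                    if cd8_row in enrich.scores.index
                    else table["tis"]
                )
                for s in ("left", "right"):
                    ids = side.index[side == s]
                    ids = [i for i in ids if i in vegfa.index]
                    if len(ids) >= 3:
                        res = stats.correlate(vegfa.loc[ids], target.loc[ids])
                        correlations[s] = {"r": res.r, "p": res.p_value, "n": res.n}
        except Exception as exc:
            raise StageError("cohort_stats", exc) from exc
        done(n_contrasts=len(results))
        summary["contrasts"] = {
            key: {
                "test": r.test_name,
                "group_sizes": list(r.group_sizes),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for key, r in results.items()
        }
        summary["vegfa_correlations"] = correlations

        # ---- stage: survival -----------------------------------------------
        done = _stage("survival")
        try:
            surv_summary: dict[str, Any] = {}
            clin = clinical.table
            for spec_item in strata_cfg:
                name = spec_item["score"]
                labels = classes[f"{name}_split"]
                if spec_item.get("cross_with"):
                    labels = classes[f"{name}_x_{spec_item['cross_with']}"]
                sub = clin
                if spec_item.get("within_side") in ("left", "right"):
                    sub = clin[clin["side"] == spec_item["within_side"]]
                ids = [i for i in sub.index if i in labels.index]
                if len(ids) < 4 or sub.loc[ids, "event"].sum() == 0:
                    warnings.warn(f"stratum {name!r}: too few usable records; skipped")
                    continue
                t = sub.loc[ids, "os_days"].to_numpy(float)
                e = sub.loc[ids, "event"].to_numpy(int)
                g = labels.loc[ids].to_numpy()
                lr = survival.logrank_test(t, e, g)
                entry: dict[str, Any] = {
                    "logrank_stat": lr.statistic,
                    "logrank_p": lr.p_value,
                    "df": lr.df,
                    "n": len(ids),
                }
                if len(pd.unique(g)) == 2:
                    x = (g == pd.unique(g)[0]).astype(float)
                    try:
                        cox = survival.cox_univariate(t, e, x)
                        entry["cox_log_hr"] = cox.log_hr
                        entry["cox_p"] = cox.p_value
                    except data_io.ValidationError as exc:
                        entry["cox_error"] = str(exc)
                key = name + (
                    f"_x_{spec_item['cross_with']}" if spec_item.get("cross_with") else ""
                )
                if spec_item.get("within_side"):
                    key += f"@{spec_item['within_side']}"
                surv_summary[key] = entry
                curves = {
                    str(lv): survival.km_estimate(t[g == lv], e[g == lv])
                    for lv in pd.unique(g)
                }
                safe = key.replace(" ", "_").replace("@", "_").replace("/", "_")
                survival.km_plot_window(curves, path=outdir / f"km_{safe}.png")
        except Exception as exc:
            raise StageError("survival", exc) from exc
        done(n_strata=len(surv_summary))
        summary["survival"] = surv_summary

        collected = sorted({str(w.message) for w in caught})

    summary["warnings"] = collected
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _resolve_score(name: str, table: pd.DataFrame, enrich) -> pd.Series:
    """A score name is either a composite column or an enrichment row."""
    if name in table.columns:
        return table[name]
    if name in enrich.scores.index:
        return enrich.scores.loc[name]
    raise KeyError(
        f"score {name!r} is neither a composite column {list(table.columns)} "
        f"nor a scored gene set"
    )
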