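"""End-to-end orchestration of the four analysis stages.

A run executes simulate -> germination metrics -> soil outcomes -> pH
growth -> integration in order, writing tidy CSV outputs per stage and a
JSON manifest recording the configuration digest, seeds, output paths, row
counts, and warnings. Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from . import establishment as est
from . import germination as germ
from . import growth_ph as gph
from . import integration as integ
from . import io_soil, synthetic_data as synth

log = logging.getLogger("lupinest")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _digest(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: Mapping | str | Path, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the full pipeline; returns (and writes) the run manifest.

    ``config`` is a mapping (or YAML path) with optional keys ``seed``,
    ``simulate`` (SimulationConfig overrides, see synthetic_data), ``inputs``
    (paths to existing germination/ordinal/growth CSVs instead of
    simulation), ``cluster_k``, ``bootstrap_reps``.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    manifest: dict = {
        "tool_version": __version__,
        "config_digest": _digest(config),
        "seed": seed,
        "stages": {},
        "warnings": [],
    }
    caught: list[str] = []

    def run_stage(name, fn):
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                outputs = fn()
            caught.extend(f"{name}: {w.message}" for w in wlist)
        except Exception as exc:  # fail fast with stage-named error
            manifest["warnings"] = caught
            _write_manifest(manifest, outdir, partial=True)
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "seconds": round(time.time() - t0, 3),
        }
        log.info("stage %s: done in %.2fs", name, time.time() - t0)

    inputs = config.get("inputs", {})
    state: dict = {}

    def stage_simulate():
        outputs = {}
        if inputs:
            for key in ("germination", "ordinal", "growth"):
                if key not in inputs:
                    raise FileNotFoundError(f"inputs.{key} missing from config")
                if not Path(inputs[key]).exists():
                    raise FileNotFoundError(f"input file not found: {inputs[key]}")
            state["trials"] = io_soil.read_table(inputs["germination"], "germination")
            state["ordinal"] = io_soil.read_table(inputs["ordinal"], "ordinal")
            state["growth"] = io_soil.read_table(inputs["growth"], "growth")
            return {k: inputs[k] for k in ("germination", "ordinal", "growth")}
        sim_cfg = synth.config_from_dict({"rng_seed": seed, **config.get("simulate", {})})
        state["trials"] = synth.simulate_germination(sim_cfg)
        state["ordinal"] = synth.simulate_soil_experiment(sim_cfg)
        state["growth"] = synth.simulate_ph_experiment(sim_cfg)
        for key, records in (("germination", state["trials"]), ("ordinal", state["ordinal"]), ("growth", state["growth"])):
            path = outdir / f"sim_{key}.csv"
            io_soil.write_table(path, records)
            outputs[key] = path
        soils_path = outdir / "soils.csv"
        io_soil.write_table(soils_path, io_soil.reference_soils())
        outputs["soil"] = soils_path
        return outputs

    def stage_germination():
        metrics = germ.metrics_table(state["trials"])
        ns = metrics[metrics["treatment"] == "NS"]
        classes = germ.classify_dormancy(ns)
        metrics = metrics.merge(classes.rename("dormancy_class"), left_on="accession_id", right_index=True, how="left")
        metrics.loc[metrics["treatment"] != "NS", "dormancy_class"] = ""
        state["germ_metrics"] = metrics
        groups = germ.trial_groups_for_logrank(state["trials"])
        lr = germ.logrank_test(groups)
        state["logrank"] = lr
        km_rows = []
        for label, (ev, cens) in groups.items():
            curve = germ.km_estimate(ev, cens)
            for t, s, r, d in zip(curve.times, curve.survival, curve.at_risk, curve.n_events):
                km_rows.append({"group": label, "day": t, "ungerminated": s, "at_risk": r, "n_events": d})
        p1 = outdir / "germination_metrics.csv"
        metrics.to_csv(p1, index=False)
        p2 = outdir / "km_curves.csv"
        pd.DataFrame(km_rows).to_csv(p2, index=False)
        p3 = outdir / "logrank.json"
        p3.write_text(json.dumps({"statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value}, indent=1))
        return {"metrics": p1, "km_curves": p2, "logrank": p3}

    def stage_soil():
        rates = est.aggregate_rates(state["ordinal"], ["species", "soil_code", "treatment"])
        matrix = est.establishment_matrix(state["ordinal"])
        state["soil_matrix"] = matrix
        coefs = est.fit_logistic(state["ordinal"], outcome="established")
        p1 = outdir / "soil_rates.csv"
        rates.to_csv(p1, index=False)
        p2 = outdir / "establishment_matrix.csv"
        matrix.to_csv(p2)
        p3 = outdir / "soil_logistic.csv"
        coefs.to_csv(p3, index=False)
        return {"rates": p1, "matrix": p2, "logistic": p3}

    def stage_growth():
        valid, excluded = gph.filter_valid(state["growth"])
        state["growth_traits"] = valid
        anova = pd.concat(
            [gph.anova_two_way(valid, resp).assign(response=resp) for resp in ("total_mm", "hypocotyl_mm", "epicotyl_mm", "ratio")],
            ignore_index=True,
        )
        contrasts = gph.pairwise_contrasts(valid, "total_mm", ["ph_level", "das"], n_perm=499, rng_seed=seed)
        p1 = outdir / "growth_traits.csv"
        valid.to_csv(p1, index=False)
        p2 = outdir / "growth_exclusions.csv"
        excluded.to_csv(p2, index=False)
        p3 = outdir / "growth_anova.csv"
        anova.to_csv(p3, index=False)
        p4 = outdir / "growth_contrasts.csv"
        contrasts.to_csv(p4, index=False)
        return {"traits": p1, "exclusions": p2, "anova": p3, "contrasts": p4}

    def stage_integrate():
        summary = gph.ph_summary(state["growth_traits"], das=14)
        isi = integ.compute_isi(summary)
        state["isi"] = isi
        metrics = state["germ_metrics"]
        ns = metrics[metrics["treatment"] == "NS"].set_index("accession_id")
        # accession-level trait table across the three experiments
        soil_mean = state["soil_matrix"].mean(axis=1).rename("soil_establishment_pct")
        table = pd.concat(
            [
                isi.set_index("accession_id")[["est_mean", "length_mean", "stability", "isi"]],
                soil_mean,
            ],
            axis=1,
        )
        table["dds50"] = ns["dds50"]  # angustifolius only; NaN elsewhere
        traits_for_ordination = table[["est_mean", "length_mean", "stability", "soil_establishment_pct"]].dropna()
        z = integ.zscore_matrix(traits_for_ordination)
        pca_res = integ.pca(z)
        k = int(config.get("cluster_k", 5))
        clus = integ.ward_cluster(z, k=k, bootstrap_reps=int(config.get("bootstrap_reps", 100)), rng_seed=seed)
        screen = integ.spearman_screen(
            table[["est_mean", "length_mean", "soil_establishment_pct", "isi"]].dropna(),
            bootstrap_reps=int(config.get("bootstrap_reps", 100)),
            rng_seed=seed,
        )
        recs = []
        for soil in state["soil_matrix"].columns:
            r = integ.recommend_accessions(state["soil_matrix"], isi.set_index("accession_id")["isi"], soil, top_n=5)
            recs.append(r.assign(soil_code=soil))
        recs = pd.concat(recs, ignore_index=True)
        p1 = outdir / "isi.csv"
        isi.to_csv(p1, index=False)
        p2 = outdir / "pca_loadings.csv"
        pca_res.loadings.to_csv(p2)
        p3 = outdir / "pca_scores.csv"
        pca_res.scores.to_csv(p3)
        p4 = outdir / "clustering.json"
        p4.write_text(
            json.dumps(
                {
                    "k": k,
                    "mean_silhouette": clus.mean_silhouette,
                    "labels": {str(a): int(l) for a, l in clus.labels.items()},
                    "merges": clus.linkage[:, :3].tolist(),
                    "node_support": [
                        {"leaves": list(map(str, row.leaves)), "support": None if pd.isna(row.support) else float(row.support)}
                        for row in clus.node_support.itertuples()
                    ],
                },
                indent=1,
            )
        )
        p5 = outdir / "correlations.csv"
        screen.to_csv(p5, index=False)
        p6 = outdir / "recommendations.csv"
        recs.to_csv(p6, index=False)
        return {"isi": p1, "pca_loadings": p2, "pca_scores": p3, "clustering": p4, "correlations": p5, "recommendations": p6}

    run_stage("simulate", stage_simulate)
    run_stage("germination", stage_germination)
    run_stage("soil", stage_soil)
    run_stage("growth", stage_growth)
    run_stage("integrate", stage_integrate)
    manifest["warnings"] = caught
    manifest["row_counts"] = {
        "germination_trials": len(state["trials"]),
        "ordinal_records": len(state["ordinal"]),
        "growth_records": len(state["growth"]),
        "accessions_isi": len(state["isi"]),
    }
    _write_manifest(manifest, outdir, partial=False)
    return manifest


def _write_manifest(manifest: dict, outdir: Path, partial: bool) -> None:
    manifest["partial"] = partial
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
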