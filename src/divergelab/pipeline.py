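"""End-to-end synthetic study: simulate -> growth -> cluster -> variants -> CNV.

``run_all`` reproduces the whole analysis chain on generated data with
planted ground truth, writing every intermediate in its documented format
plus a JSON summary.  Outputs are byte-identical across reruns with the
same configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as dio
from .cluster import classify_strategy, select_model
from .config import RunConfig, save_config
from .ecoevo import UptakeParams, run_treatment, trait_clusters
from .growth import rates_from_table
from .synth import (
    StudyDesign,
    library_size,
    population_sample_count,
    simulate_coverage,
    simulate_growth_table,
    simulate_variant_tables,
)
from .tradeoff import TradeoffCurve
from .variants import call_cnv, candidate_loci, mutation_spectrum, subtract_ancestral

logger = logging.getLogger("divergelab")

__all__ = ["run_all"]


def _simulate_stage(cfg: RunConfig, outdir: Path) -> dict:
    curve = TradeoffCurve(cfg.tradeoff_p)
    params = UptakeParams()
    summary = {}
    for tr in cfg.treatments:
        traj = run_treatment(
            tr,
            curve,
            params,
            days=cfg.days,
            seed=cfg.stage_seed(f"simulate:{tr}"),
            mutation_sd=cfg.mutation_sd,
        )
        df = traj.to_dataframe()
        df.to_csv(outdir / f"trajectory_{tr}.csv", index=False, float_format="%.10g")
        final = traj.final
        clusters = trait_clusters(final.u1, final.density)
        summary[tr] = {
            "n_trait_clusters": len(clusters),
            "cluster_u1": [round(u, 4) for u, _ in clusters],
            "generations": round(final.generations, 2),
            "final_D": final.D,
            "washout": traj.washout,
        }
        logger.info("simulate[%s]: %d clusters, %.0f generations", tr, len(clusters), final.generations)
    return summary


def _growth_stage(cfg: RunConfig, outdir: Path) -> dict:
    # growth curves for a panel of FS/GS-like genotypes on both sugars
    rng = np.random.default_rng(cfg.stage_seed("growth:panel"))
    genotype_mu = {}
    panel = {}
    for i in range(4):
        panel[f"FS_{i}"] = {"fructose": 0.82, "galactose": 0.35}
        panel[f"GS_{i}"] = {"fructose": 0.43, "galactose": 0.70}
    for genotype, rates in panel.items():
        for sugar, mu in rates.items():
            genotype_mu[(genotype, sugar)] = mu * float(1 + 0.05 * rng.standard_normal())
    # deep-exponential curves (cuvette-equivalent depths): the window
    # protocol is unbiased only while saturation stays far above the
    # OD > 0.16 eligibility threshold
    table, truth = simulate_growth_table(
        genotype_mu,
        n_replicates=cfg.n_replicates,
        seed=cfg.stage_seed("growth:curves"),
        noise_sd=cfg.noise_sd,
        K=6.0,
        inoculum=0.005,
        duration_h=30.0,
    )
    dio.write_growth_table(table, outdir / "plates.csv")
    rates = rates_from_table(table, window=cfg.window, min_od=cfg.min_od)
    dio.write_rates(rates, outdir / "rates.csv")
    merged = rates.merge(truth, on=["genotype", "sugar"])
    err = float(np.median(np.abs(merged["mu_max"] - merged["true_mu"])))
    logger.info("growth: median |mu error| = %.4f 1/h over %d genotype-sugar pairs", err, len(merged))
    return {"median_abs_mu_error": err, "n_rates": len(rates)}


def _cluster_stage(cfg: RunConfig, outdir: Path) -> dict:
    rates = dio.read_rates(outdir / "rates.csv")
    wide = rates.pivot(index="genotype", columns="sugar", values="mu_max")
    pts = wide[["galactose", "fructose"]].to_numpy()
    model = select_model(pts, k_max=cfg.k_max, seed=cfg.stage_seed("cluster"))
    labels = [classify_strategy(tuple(m)) for m in model.means]
    rows = []
    for j in range(model.k):
        rows.append(
            {
                "cluster": j,
                "mean_g": model.means[j, 0],
                "mean_f": model.means[j, 1],
                "weight": model.weights[j],
                "label": labels[j],
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "clusters.csv", index=False, float_format="%.10g")
    logger.info("cluster: k=%d labels=%s", model.k, labels)
    return {"k": model.k, "labels": labels, "bic": model.bic}


def _variant_stage(cfg: RunConfig, outdir: Path) -> dict:
    design = StudyDesign()
    evolved, ancestral, meta, truth = simulate_variant_tables(
        design, seed=cfg.stage_seed("variants")
    )
    dio.write_variants_vcf(evolved, outdir / "evolved.vcf")
    dio.write_variants_vcf(ancestral, outdir / "ancestral.vcf")
    dio.write_meta(meta, outdir / "meta.csv")
    evolved_rt = dio.read_variants_vcf(outdir / "evolved.vcf")
    ancestral_rt = dio.read_variants_vcf(outdir / "ancestral.vcf")
    derived = subtract_ancestral(evolved_rt, ancestral_rt)
    loci = candidate_loci(
        derived,
        meta,
        min_strains=cfg.min_strains,
        min_variants=cfg.min_variants,
        strict_exclusive=cfg.strict_exclusive,
    )
    loci.to_csv(outdir / "loci.csv", index=False)
    retained = sorted(loci.loc[loci["retained"], "locus"])
    spectrum = mutation_spectrum(derived)
    logger.info("variants: retained loci %s", retained)
    return {
        "retained_loci": retained,
        "planted_loci": sorted(truth["planted"]),
        "spectrum": {k: round(v, 4) for k, v in spectrum.items()},
        "library_size": library_size(design),
        "population_samples": population_sample_count(design),
    }


def _cnv_stage(cfg: RunConfig, outdir: Path) -> dict:
    planted = [
        {"start_bin": 200, "n_bins": 50, "copy": 6.0},
        {"start_bin": 600, "n_bins": 40, "copy": 3.0},
        {"start_bin": 1000, "n_bins": 60, "copy": 2.0},
        {"start_bin": 1500, "n_bins": 10, "copy": 0.0},
    ]
    track, truth = simulate_coverage(
        genome_len=cfg.genome_len,
        mean_depth=cfg.mean_depth,
        planted=planted,
        bin_size=cfg.bin_size,
        seed=cfg.stage_seed("cnv"),
    )
    dio.write_coverage(track, outdir / "coverage.tsv")
    track_rt = dio.read_coverage(outdir / "coverage.tsv")
    calls = call_cnv(
        track_rt,
        dup_ratio=cfg.dup_ratio,
        del_ratio=cfg.del_ratio,
        min_bins=cfg.min_bins,
    )
    dio.write_cnv_bed(calls, outdir / "cnv.bed")
    logger.info("cnv: %d calls for %d planted events", len(calls), len(truth))
    return {
        "n_calls": len(calls),
        "n_planted": len(truth),
        "calls": [
            {"start": c.start, "end": c.end, "type": c.type, "copy_ratio": round(c.copy_ratio, 3)}
            for c in calls
        ],
    }


def run_all(cfg: RunConfig, outdir) -> dict:
    """Run the full synthetic study; returns (and writes) the summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.yaml")
    report = {"seed": cfg.seed}
    for name, stage in [
        ("simulate", _simulate_stage),
        ("growth", _growth_stage),
        ("cluster", _cluster_stage),
        ("variants", _variant_stage),
        ("cnv", _cnv_stage),
    ]:
        try:
            report[name] = stage(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
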