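"""Synthetic study-design inputs with planted ground truth.

Emulates the data shapes of a two-sugar chemostat evolution experiment:
three treatments (fructose, galactose, mix) x four replicate bioreactors
x three sampled timepoints, six colonies picked per plate (mix samples
are plated on both sugar plates), plate-reader OD600 curves at 10-min
resolution, 2-D (G_max, F_max) phenotype clouds, per-strain variant
tables, and binned coverage tracks at mean depth 300.  Every generator is
deterministic under a fixed seed and returns its ground truth alongside
the data, so downstream estimators can be tested for recovery without
reaching into generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .variants import CoverageTrack

__all__ = [
    "StudyDesign",
    "library_size",
    "population_sample_count",
    "simulate_growth_curve",
    "simulate_phenotype_clouds",
    "simulate_variant_tables",
    "simulate_coverage",
    "CNV_PRESETS",
]


@dataclass(frozen=True)
class StudyDesign:
    """Counts defining the sampling layout of the evolution experiment."""

    treatments: tuple[str, ...] = ("fructose", "galactose", "mix")
    replicates_per_treatment: int = 4
    timepoints: int = 3
    colonies_per_plate: int = 6
    mix_plated_on_both: bool = True
    strains_per_replicate_sequenced: int = 3
    replicates_sequenced_per_treatment: int = 2

    def __post_init__(self) -> None:
        for name in (
            "replicates_per_treatment",
            "timepoints",
            "colonies_per_plate",
            "strains_per_replicate_sequenced",
            "replicates_sequenced_per_treatment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def plates_per_population(self, treatment: str) -> int:
        return 2 if (treatment == "mix" and self.mix_plated_on_both) else 1


def library_size(design: StudyDesign) -> int:
    """Total single-genotype strains picked across the whole design.

    Six colonies per plate, one plate per population sample except the
    mix treatment which is plated on both sugars — the paper-scale
    default design yields 288 strains.
    """
    total = 0
    for tr in design.treatments:
        total += (
            design.timepoints
            * design.replicates_per_treatment
            * design.colonies_per_plate
            * design.plates_per_population(tr)
        )
    return total


def population_sample_count(design: StudyDesign) -> int:
    """Metagenomic population samples: one per replicate per timepoint."""
    return len(design.treatments) * design.replicates_per_treatment * design.timepoints


# ---------------------------------------------------------------------------
# Growth curves


def simulate_growth_curve(
    mu: float,
    lag_h: float = 1.0,
    K: float = 1.2,
    inoculum: float = 0.01,
    noise_sd: float = 0.01,
    blank: float = 0.09,
    seed: int = 0,
    duration_h: float = 24.0,
    dt_min: float = 10.0,
) -> tuple[GrowthCurve, dict]:
    """Lagged-logistic OD600 curve with multiplicative noise on a 10-min grid.

    The noise-free signal is ``K * x0 / (x0 + (K - x0) e^{-mu (t - lag)})``
    (flat at the inoculum during the lag), shifted by the blank and
    multiplied by lognormal-style noise ``(1 + noise_sd * z)``.  Returns
    the curve and a truth dict with the generator settings and the
    noise-free signal.
    """
    if not mu > 0:
        raise ValueError("mu must be positive")
    if not K > inoculum > 0:
        raise ValueError("need K > inoculum > 0")
    rng = np.random.default_rng(seed)
    t_min = np.arange(0.0, duration_h * 60.0 + 0.5 * dt_min, dt_min)
    t_h = t_min / 60.0
    te = np.maximum(t_h - lag_h, 0.0)
    signal = K * inoculum / (inoculum + (K - inoculum) * np.exp(-mu * te))
    noise = 1.0 + noise_sd * rng.standard_normal(len(t_min))
    od = signal * noise + blank
    curve = GrowthCurve(t_min, od, blank_od600=blank)
    truth = {
        "mu": mu,
        "lag_h": lag_h,
        "K": K,
        "inoculum": inoculum,
        "noise_sd": noise_sd,
        "blank": blank,
        "signal": signal,
    }
    return curve, truth


def simulate_growth_table(
    genotype_mu: dict[tuple[str, str], float],
    n_replicates: int = 3,
    seed: int = 0,
    **curve_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format plate table for (genotype, sugar) -> true mu settings.

    Returns (table, truth) where truth has one row per genotype x sugar.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for (genotype, sugar), mu in sorted(genotype_mu.items()):
        truth_rows.append({"genotype": genotype, "sugar": sugar, "true_mu": mu})
        for rep in range(1, n_replicates + 1):
            curve, _ = simulate_growth_curve(
                mu, seed=int(rng.integers(2**31)), **curve_kwargs
            )
            for t, od in zip(curve.time_min, curve.od600):
                rows.append(
                    {
                        "genotype": genotype,
                        "sugar": sugar,
                        "replicate": rep,
                        "time_min": t,
                        "od600": od,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Phenotype clouds

# Cluster geometry (G_max, F_max means, 1/h) mimicking the observed
# specialist clusters: FS fast on fructose, GS fast on galactose.
DEFAULT_COMPONENTS = {
    "FS": {"mean": (0.35, 0.75), "sd": 0.03},
    "GS": {"mean": (0.70, 0.45), "sd": 0.03},
}


def simulate_phenotype_clouds(
    components: dict[str, dict] | None = None,
    n_per_component: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian (G_max, F_max) clouds with truth labels.

    ``components`` maps label -> {"mean": (g, f), "sd": scalar or
    "cov": 2x2}.  Returns (points, labels) with labels aligned to rows.
    """
    if components is None:
        components = DEFAULT_COMPONENTS
    rng = np.random.default_rng(seed)
    pts = []
    labels = []
    for label in sorted(components):
        spec = components[label]
        mean = np.asarray(spec["mean"], dtype=float)
        cov = np.asarray(
            spec.get("cov", np.eye(2) * float(spec.get("sd", 0.03)) ** 2), dtype=float
        )
        if np.allclose(cov, 0):
            draw = np.tile(mean, (n_per_component, 1))
        else:
            draw = rng.multivariate_normal(mean, cov, size=n_per_component)
        pts.append(np.clip(draw, 0.0, None))
        labels.extend([label] * n_per_component)
    return np.vstack(pts), np.array(labels)


# ---------------------------------------------------------------------------
# Variant tables


def _sequenced_strains(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Strain metadata for the sequencing subsample of the design.

    Per treatment and timepoint, strains are drawn from a fixed subset of
    replicates.  Phenotype labels follow the treatment: fructose-treatment
    strains are FS, galactose GS, and mix strains alternate FS/GS (the
    coexisting pair).
    """
    rows = []
    for tr in design.treatments:
        reps = range(1, design.replicates_sequenced_per_treatment + 1)
        for rep in reps:
            for tp in range(1, design.timepoints + 1):
                for s in range(design.strains_per_replicate_sequenced):
                    if tr == "fructose":
                        pheno = "FS"
                    elif tr == "galactose":
                        pheno = "GS"
                    else:
                        pheno = "FS" if s % 2 == 0 else "GS"
                    rows.append(
                        {
                            "strain": f"{tr[0].upper()}{rep}_t{tp}_s{s}",
                            "treatment": tr,
                            "phenotype": pheno,
                            "replicate": rep,
                            "timepoint": f"T{tp}",
                        }
                    )
    return pd.DataFrame(rows)


DEFAULT_CLASS_MIX = {"CNV_dup": 0.70, "CNV_del": 0.19, "SNP": 0.08, "indel": 0.03}


def simulate_variant_tables(
    design: StudyDesign | None = None,
    planted_fs_loci: tuple[str, ...] = ("fbp", "pfk"),
    planted_gs_loci: tuple[str, ...] = ("pgmA", "ptnABCD", "ldh"),
    noise_loci_rate: float = 2.0,
    class_mix: dict[str, float] | None = None,
    min_carriers: int = 5,
    n_ancestral_shared: int = 5,
    genome_length: int = 2_500_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Evolved + ancestral variant tables for the sequencing design.

    Planted loci receive SNP/indel variants in >= ``min_carriers``
    carrier strains of the matching phenotype only; noise loci are
    scattered with a Poisson(noise_loci_rate) count per strain, each at
    its own random unannotated locus; ancestral shared variants appear in
    every strain and in the ancestor table (they must vanish under
    ancestral subtraction).  Returns (evolved, ancestral, meta, truth).
    """
    if design is None:
        design = StudyDesign()
    if class_mix is None:
        class_mix = DEFAULT_CLASS_MIX
    rng = np.random.default_rng(seed)
    meta = _sequenced_strains(design, rng)
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    pos_grid = np.arange(1000, genome_length, 150)
    positions = iter(rng.choice(pos_grid, size=min(len(pos_grid), 10000), replace=False))
    records = []
    truth_carriers: dict[str, list[str]] = {}
    for pheno, loci in (("FS", planted_fs_loci), ("GS", planted_gs_loci)):
        carriers_pool = meta.loc[meta["phenotype"] == pheno, "strain"].tolist()
        for gene in loci:
            pos = int(next(positions))
            n_car = min(
                len(carriers_pool),
                int(rng.integers(min_carriers, min_carriers + 3)),
            )
            carriers = list(rng.choice(carriers_pool, size=n_car, replace=False))
            truth_carriers[gene] = carriers
            for strain in carriers:
                records.append(
                    {
                        "strain": strain,
                        "gene": gene,
                        "position": pos,
                        "var_class": "SNP",
                        "annotated": True,
                    }
                )
    # background noise: private, unannotated loci
    noise_count = 0
    for strain in meta["strain"]:
        for _ in range(rng.poisson(noise_loci_rate)):
            pos = int(next(positions))
            records.append(
                {
                    "strain": strain,
                    "gene": f"noise_{pos}",
                    "position": pos,
                    "var_class": classes[rng.choice(len(classes), p=probs)],
                    "annotated": bool(rng.random() < 0.3),
                }
            )
            noise_count += 1
    # ancestral shared variants, present everywhere and in the ancestor
    ancestral_records = []
    for _ in range(n_ancestral_shared):
        pos = int(next(positions))
        ancestral_records.append(
            {
                "strain": "ancestor",
                "gene": f"anc_{pos}",
                "position": pos,
                "var_class": "SNP",
                "annotated": True,
            }
        )
        for strain in meta["strain"]:
            records.append(
                {
                    "strain": strain,
                    "gene": f"anc_{pos}",
                    "position": pos,
                    "var_class": "SNP",
                    "annotated": True,
                }
            )
    evolved = pd.DataFrame(records, columns=["strain", "gene", "position", "var_class", "annotated"])
    ancestral = pd.DataFrame(
        ancestral_records, columns=["strain", "gene", "position", "var_class", "annotated"]
    )
    truth = {
        "planted": {**{g: "FS" for g in planted_fs_loci}, **{g: "GS" for g in planted_gs_loci}},
        "carriers": truth_carriers,
        "n_noise": noise_count,
        "ancestral_positions": [r["position"] for r in ancestral_records],
    }
    return evolved, ancestral, meta, truth


# ---------------------------------------------------------------------------
# Coverage tracks

# Motifs from the observed CNV repertoire: multi-fold duplications of the
# pgmA region (6x) and tandem-duplicated segments (2x, 3x), plus full
# deletions.
CNV_PRESETS = {
    "pgmA_6x": {"copy": 6.0, "length_bp": 5000},
    "dup_3x": {"copy": 3.0, "length_bp": 4000},
    "dup_2x": {"copy": 2.0, "length_bp": 6000},
    "del_full": {"copy": 0.0, "length_bp": 1000},
}


def simulate_coverage(
    genome_len: int = 200_000,
    mean_depth: float = 300.0,
    planted: list[dict] | None = None,
    bin_size: int = 100,
    seed: int = 0,
) -> tuple[CoverageTrack, list[dict]]:
    """Poisson binned depth with planted copy-number events.

    ``planted`` is a list of ``{"start_bin", "n_bins", "copy"}`` dicts
    (copy is the fold change: 0 deletes, 6 is a six-fold duplication).
    Per-bin depth ~ Poisson(mean_depth * copy).  Returns the track and
    the planted truth (with 1-based coordinates added).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    n_bins = genome_len // bin_size
    lam = np.full(n_bins, float(mean_depth))
    truth = []
    for event in planted or []:
        i0 = int(event["start_bin"])
        n = int(event["n_bins"])
        copy = float(event["copy"])
        if i0 < 0 or i0 + n > n_bins:
            raise ValueError("planted event outside the genome")
        lam[i0 : i0 + n] = mean_depth * copy
        truth.append(
            {
                **event,
                "start": i0 * bin_size + 1,
                "end": (i0 + n) * bin_size,
                "type": "del" if copy < 1.0 else "dup",
            }
        )
    depth = rng.poisson(lam).astype(float)
    return CoverageTrack(depth, bin_size=bin_size, genome_length=n_bins * bin_size), truth
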