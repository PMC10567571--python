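"""Synthetic two-platform plasma-proteogenomics cohort generator.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* LD-block genotypes from a per-block latent Gaussian copula
  (latent correlation ``exp(-distance * ld_decay)`` between variant
  positions, thresholded to per-variant allele frequencies), with a
  frequency spectrum that produces rare variants, and optionally a second
  population with faster LD decay (smaller high-LD classes, emulating
  African-ancestry cohorts).
* Log-normal protein abundances with a cis effect near the encoding
  gene's TSS, shared and pleiotropic trans effects, and between-donor
  biological noise.
* Two assay platforms ("A": antibody-based, paired assays, core +
  expansion panel sets; "B": aptamer-based, occasionally two assays per
  target) with platform-specific technical noise, plate (batch) effects,
  LOD censoring (values below the LOD are retained but flagged), duplicate
  measurements, and epitope-effect protein-altering variants that shift the
  *measured* level on one platform only and never the true level.
* Liability-threshold binary phenotypes and linear quantitative traits
  driven by true protein levels, with a synthetic trait-hit catalogue as a
  GWAS-catalogue analogue.

Every simulated effect is recorded in a :class:`TruthLedger`; analysis
modules never read the ledger — tests compare analysis output to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, VARIANT_COLUMNS

__all__ = [
    "ConfigError",
    "SimConfig",
    "TruthLedger",
    "SimulatedCohort",
    "load_cohort",
    "sim_genotypes",
    "sim_proteome",
    "sim_measurements",
    "sim_phenotypes",
    "simulate_cohort",
]


class ConfigError(ValueError):
    """Degenerate or inconsistent simulation configuration."""


def _default_trans_network() -> List[dict]:
    # one pleiotropic hub hitting >50 proteins plus a small specific module
    return [
        {"variant": "common:0", "proteins": list(range(0, 55)), "effect": 0.25},
        {"variant": "common:1", "proteins": [55, 56, 57], "effect": 0.4},
    ]


def _default_phenotypes() -> dict:
    return {
        "binary": [
            {"name": "disease_1", "weights": {0: 1.0}, "prevalence": 0.1},
        ],
        "quantitative": [
            {"name": "trait_1", "weights": {1: 0.5}, "noise_sd": 1.0},
        ],
    }


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Platform-specific parameters are keyed by platform label; platform "A"
    defaults emulate an antibody platform (higher technical noise, more
    below-LOD values), platform "B" an aptamer platform.  The default noise
    s.d. values 0.164 and 0.099 correspond to log-normal duplicate CVs of
    about 16.5% and 9.9%; biological s.d. 0.42 puts random-pair CVs in the
    30-50% range.
    """

    seed: int = 0
    n_donors: int = 2000
    n_populations: int = 1
    n_blocks: int = 10
    variants_per_block: int = 25
    block_span_bp: int = 1_000_000
    ld_decay: Union[float, Sequence[float]] = 2e-6
    maf_spectrum: dict = field(default_factory=lambda: {
        "kind": "loguniform", "min": 5e-4, "max": 0.5})
    n_proteins: int = 60
    shared_target_fraction: float = 0.6
    cis_effect_sd: float = 0.5
    biological_sd: float = 0.42
    trans_network: List[dict] = field(default_factory=_default_trans_network)
    epitope_pav_prob: float = 0.1
    platform_noise_sd: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.164, "B": 0.099})
    lod_quantile: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.05, "B": 0.01})
    plate_effect_sd: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.05, "B": 0.08})
    duplicate_fraction: float = 0.03
    plate_size: int = 96
    multi_assay_prob_b: float = 0.1
    phenotype_spec: dict = field(default_factory=_default_phenotypes)

    def __post_init__(self) -> None:
        if self.variants_per_block <= 0 or self.n_blocks <= 0:
            raise ConfigError("need at least one block and one variant per block")
        if self.n_donors < 2:
            raise ConfigError("need at least two donors")
        if self.n_populations not in (1, 2):
            raise ConfigError("n_populations must be 1 or 2")
        for frac in (self.shared_target_fraction, self.epitope_pav_prob,
                     self.duplicate_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError("fractions must lie in [0, 1]")
        for sd in (self.cis_effect_sd, self.biological_sd,
                   *self.platform_noise_sd.values(),
                   *self.plate_effect_sd.values()):
            if sd < 0:
                raise ConfigError("standard deviations must be >= 0")
        for pheno in self.phenotype_spec.get("binary", []):
            if not (0.0 < pheno["prevalence"] < 1.0):
                raise ConfigError(
                    f"prevalence {pheno['prevalence']} outside (0,1)")

    def decay_for(self, population: int) -> float:
        if np.isscalar(self.ld_decay):
            return float(self.ld_decay)
        return float(self.ld_decay[population])

    def population_sizes(self) -> List[int]:
        sizes = [self.n_donors // self.n_populations] * self.n_populations
        sizes[0] += self.n_donors - sum(sizes)
        return sizes


@dataclass
class TruthLedger:
    """Ground truth of the generative model, for parameter-recovery tests."""

    cis_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    trans_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    epitope_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    baselines: Dict[str, float] = field(default_factory=dict)
    phenotype_weights: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    panel: pd.DataFrame
    protein_matrices: Dict[str, pd.DataFrame]
    samples: pd.DataFrame
    phenotypes: pd.DataFrame
    trait_hits: pd.DataFrame
    # generative context; absent when a cohort is loaded from disk
    config: Optional[SimConfig] = None
    pop_frequencies: Optional[pd.DataFrame] = None
    true_log_levels: Optional[pd.DataFrame] = None  # donors x target_id
    ledger: Optional[TruthLedger] = None

    def write(self, outdir) -> None:
        """Write every public artefact (not the ledger) as TSV."""
        import os

        from . import io as pio

        os.makedirs(outdir, exist_ok=True)
        pio.write_genotypes(self.variants, self.genotypes,
                            os.path.join(outdir, "genotypes"))
        pio.write_assay_panel(self.panel, os.path.join(outdir, "assay_panel.tsv"))
        for platform, matrix in self.protein_matrices.items():
            pio.write_protein_matrix(
                matrix, os.path.join(outdir, f"protein_{platform}.tsv"))
        pio.write_table(self.samples, os.path.join(outdir, "samples.tsv"))
        pio.write_table(self.phenotypes, os.path.join(outdir, "phenotypes.tsv"))
        pio.write_table(self.trait_hits, os.path.join(outdir, "trait_hits.tsv"))


# ---------------------------------------------------------------------------
# genotypes


def _draw_frequencies(spec: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec.get("kind", "loguniform")
    if kind == "loguniform":
        lo, hi = spec.get("min", 5e-4), spec.get("max", 0.5)
        maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))
    elif kind == "beta":
        maf = rng.beta(spec.get("a", 0.5), spec.get("b", 2.0), size=size) / 2
        maf = np.clip(maf, spec.get("min", 1e-5), 0.5)
    elif kind == "fixed":
        maf = np.full(size, float(spec["value"]))
    else:
        raise ConfigError(f"unknown maf_spectrum kind {kind!r}")
    # alt allele is minor or major with equal probability; the flip is
    # applied by recoding dosages (2 - d), which preserves LD exactly
    flip = rng.random(size) < 0.5
    return maf, flip


def _block_layout(config: SimConfig, rng: np.random.Generator):
    """Chromosome, start offset and sorted positions for each block."""
    layout = []
    n_chroms = max(1, min(5, config.n_blocks))
    for b in range(config.n_blocks):
        chrom = f"chr{(b % n_chroms) + 1}"
        # blocks on the same chromosome are spaced 10x the span apart so
        # that between-block LD and region chaining are both negligible
        start = 1 + (b // n_chroms) * 10 * config.block_span_bp
        pos = np.sort(rng.integers(start, start + config.block_span_bp,
                                   size=config.variants_per_block))
        pos = np.unique(pos)
        while len(pos) < config.variants_per_block:
            extra = rng.integers(start, start + config.block_span_bp,
                                 size=config.variants_per_block - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        layout.append((chrom, pos[:config.variants_per_block]))
    return layout


def _simulate_block_dosages(pos: np.ndarray, alt_freq: np.ndarray,
                            n_donors: int, decay: float,
                            rng: np.random.Generator) -> np.ndarray:
    m = len(pos)
    corr = np.exp(-decay * np.abs(pos[:, None] - pos[None, :]))
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    z = rng.standard_normal((2 * n_donors, m)) @ chol.T
    thresh = stats.norm.ppf(alt_freq)
    haps = (z < thresh).astype(float)
    return haps[:n_donors] + haps[n_donors:]


def sim_genotypes(config: SimConfig,
                  rng: Optional[np.random.Generator] = None):
    """Simulate LD-block genotypes.

    Returns ``(VariantTable, GenotypeMatrix, pop_frequencies)`` where
    ``pop_frequencies`` holds the generative per-population alternate-allele
    frequencies.  The variant table reports realized frequencies over the
    whole cohort, with info scores of 1 (the dosages are exact).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout = _block_layout(config, rng)
    n_pops = config.n_populations
    pop_sizes = config.population_sizes()

    variant_rows, freq_rows, dose_cols = [], [], []
    pop_blocks: List[List[np.ndarray]] = [[] for _ in range(n_pops)]
    for b, (chrom, pos) in enumerate(layout):
        drawn = [_draw_frequencies(config.maf_spectrum, len(pos), rng)
                 for _ in range(n_pops)]
        flip = drawn[0][1]  # alt-allele orientation is shared across pops
        pop_freqs = []
        for p in range(n_pops):
            maf = drawn[p][0]
            dose = _simulate_block_dosages(
                pos, maf, pop_sizes[p], config.decay_for(p), rng)
            dose[:, flip] = 2.0 - dose[:, flip]
            pop_blocks[p].append(dose)
            pop_freqs.append(np.where(flip, 1.0 - maf, maf))
        block_dose = np.vstack([pop_blocks[p][b] for p in range(n_pops)])
        dose_cols.append(block_dose)
        for j, position in enumerate(pos):
            vid = f"{chrom}:{position}:{b}:{j}"
            realized = float(block_dose[:, j].mean() / 2)
            variant_rows.append({
                "variant_id": vid, "chrom": chrom, "pos": int(position),
                "ref_allele": "A", "alt_allele": "G",
                "alt_freq": realized,
                "maf": min(realized, 1 - realized), "info": 1.0,
            })
            freq_rows.append({"variant_id": vid, "block": b, **{
                f"alt_freq_pop{p + 1}": float(pop_freqs[p][j])
                for p in range(n_pops)}})

    variants = pd.DataFrame(variant_rows, columns=VARIANT_COLUMNS)
    dosages = np.hstack(dose_cols)
    donors = [f"D{i:05d}" for i in range(config.n_donors)]
    genotypes = GenotypeMatrix(donors, variants["variant_id"], dosages)
    return variants, genotypes, pd.DataFrame(freq_rows)


# ---------------------------------------------------------------------------
# proteome


def _resolve_variant(ref: Union[int, str], variants: pd.DataFrame) -> str:
    """Resolve a trans-network variant reference to a variant_id."""
    if isinstance(ref, (int, np.integer)):
        if not (0 <= ref < len(variants)):
            raise ConfigError(f"trans_network variant index {ref} out of range")
        return str(variants["variant_id"].iloc[int(ref)])
    ref = str(ref)
    if ref.startswith("common:"):
        k = int(ref.split(":", 1)[1])
        order = variants.sort_values("maf", ascending=False, kind="mergesort")
        if k >= len(order):
            raise ConfigError(f"trans_network rank {k} out of range")
        return str(order["variant_id"].iloc[k])
    if ref not in set(variants["variant_id"]):
        raise ConfigError(f"trans_network references unknown variant {ref!r}")
    return ref


def sim_proteome(config: SimConfig, variants: pd.DataFrame,
                 genotypes: GenotypeMatrix,
                 rng: Optional[np.random.Generator] = None):
    """Simulate true (pre-measurement) log protein levels and the panel.

    True log-level = baseline + cis effect * dosage + trans effects +
    biological noise.  Epitope protein-altering variants are only recorded
    here (flagged per platform in the ledger); they shift measured levels in
    :func:`sim_measurements` and never the true levels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_donors
    n_prot = config.n_proteins
    target_ids = [f"P{i:04d}" for i in range(n_prot)]

    by_chrom = variants.groupby("chrom")
    blocks = sorted(variants["chrom"].unique())
    baselines = rng.uniform(2.0, 8.0, size=n_prot)

    cis_rows, epitope_rows, panel_rows = [], [], []
    true_levels = np.tile(baselines, (n, 1)).astype(float)

    n_shared = int(round(config.shared_target_fraction * n_prot))
    for i, target in enumerate(target_ids):
        chrom = blocks[i % len(blocks)]
        chrom_variants = by_chrom.get_group(chrom)
        anchor = chrom_variants.sample(1, random_state=rng.integers(2**31)).iloc[0]
        tss = int(anchor["pos"])
        window = chrom_variants[
            (chrom_variants["pos"] - tss).abs() <= 1_000_000]
        common = window[window["maf"] >= 0.01]
        pool = common if len(common) else window
        cis_variant = str(pool["variant_id"].iloc[
            int(rng.integers(len(pool)))])
        beta = float(rng.normal(0.0, config.cis_effect_sd))
        true_levels[:, i] += beta * genotypes.dosage(cis_variant)
        cis_rows.append({"target_id": target, "variant_id": cis_variant,
                         "beta": beta, "tss": tss, "chrom": chrom})

        shared = i < n_shared
        on_a = shared or (i % 2 == 0)
        on_b = shared or (i % 2 == 1)
        dilution = _dilution_group(baselines[i], baselines)
        subcellular = str(rng.choice(
            ["secreted", "membrane", "intracellular"], p=[0.25, 0.27, 0.48]))
        if on_a:
            panel_rows.append({
                "assay_id": f"A_{target}", "platform": "A",
                "target_id": target, "target_chrom": chrom,
                "target_tss": tss, "dilution_group": dilution,
                "lod": np.nan,
                "panel_set": "core" if rng.random() < 0.5 else "expansion",
                "subcellular_class": subcellular,
            })
        if on_b:
            n_b = 2 if (shared and rng.random() < config.multi_assay_prob_b) else 1
            for k in range(n_b):
                suffix = "" if k == 0 else f"_{k + 1}"
                panel_rows.append({
                    "assay_id": f"B_{target}{suffix}", "platform": "B",
                    "target_id": target, "target_chrom": chrom,
                    "target_tss": tss, "dilution_group": dilution,
                    "lod": np.nan, "panel_set": "",
                    "subcellular_class": subcellular,
                })
        # platform-specific epitope artifact at a PAV near the TSS
        if shared and rng.random() < config.epitope_pav_prob:
            others = window[window["variant_id"] != cis_variant]
            others = others[others["maf"] >= 0.01] if \
                (others["maf"] >= 0.01).any() else others
            if len(others):
                pav = str(others["variant_id"].iloc[
                    int(rng.integers(len(others)))])
                platform = "A" if rng.random() < 0.5 else "B"
                effect = float(rng.choice([-1.0, 1.0]) *
                               rng.uniform(0.5, 1.0))
                epitope_rows.append({
                    "target_id": target, "variant_id": pav,
                    "platform": platform, "effect": effect,
                })

    trans_rows = []
    for entry in config.trans_network:
        vid = _resolve_variant(entry["variant"], variants)
        dose = genotypes.dosage(vid)
        for pi in entry["proteins"]:
            if not (0 <= pi < n_prot):
                raise ConfigError(
                    f"trans_network protein index {pi} out of range")
            true_levels[:, pi] += float(entry["effect"]) * dose
            trans_rows.append({"target_id": target_ids[pi],
                               "variant_id": vid,
                               "beta": float(entry["effect"])})

    true_levels += rng.normal(0.0, config.biological_sd, size=(n, n_prot))

    panel = pd.DataFrame(panel_rows)
    ledger = TruthLedger(
        cis_effects=pd.DataFrame(cis_rows),
        trans_effects=pd.DataFrame(trans_rows),
        epitope_effects=pd.DataFrame(
            epitope_rows, columns=["target_id", "variant_id", "platform",
                                   "effect"]),
        baselines=dict(zip(target_ids, baselines)),
    )
    true_df = pd.DataFrame(true_levels, index=pd.Index(genotypes.donors,
                                                       name="donor_id"),
                           columns=target_ids)
    return panel, true_df, ledger


def _dilution_group(value: float, all_values: np.ndarray) -> str:
    """Abundant proteins are run at high dilution."""
    lo, hi = np.quantile(all_values, [1 / 3, 2 / 3])
    if value < lo:
        return "low"
    if value < hi:
        return "mid"
    return "high"


# ---------------------------------------------------------------------------
# measurements


def sim_measurements(config: SimConfig, genotypes: GenotypeMatrix,
                     panel: pd.DataFrame, true_log_levels: pd.DataFrame,
                     ledger: TruthLedger,
                     rng: Optional[np.random.Generator] = None):
    """Turn true log levels into per-platform measured raw levels.

    measured log-level = true + epitope term * dosage (one platform only)
    + plate effect + platform noise; raw level = exp(log-level).  The assay
    LOD is set at the configured per-platform quantile of the measured
    distribution; values below the LOD are retained.  A configured fraction
    of donors is measured twice on the same plate with symmetric duplicate
    links.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    donors = list(true_log_levels.index)
    n = len(donors)
    samples = pd.DataFrame({
        "donor_id": donors,
        "sex": rng.choice(["F", "M"], size=n),
        "age": rng.integers(40, 71, size=n),
        "sample_age": np.round(rng.uniform(0.0, 10.0, size=n), 2),
        "population": [f"pop{p + 1}"
                       for p, size in enumerate(config.population_sizes())
                       for _ in range(size)],
    })

    epitope = ledger.epitope_effects
    n_dup = int(round(config.duplicate_fraction * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)

    matrices: Dict[str, pd.DataFrame] = {}
    lods: Dict[str, float] = {}
    for platform in sorted(panel["platform"].unique()):
        plat_panel = panel[panel["platform"] == platform]
        noise_sd = config.platform_noise_sd[platform]
        plate_sd = config.plate_effect_sd[platform]
        # donors fill plates sequentially
        plate_of = np.array([f"{platform}_plate_{i // config.plate_size:03d}"
                             for i in range(n)])
        plate_ids = sorted(set(plate_of))
        plate_shift = dict(zip(plate_ids,
                               rng.normal(0.0, plate_sd, size=len(plate_ids))))
        shifts = np.array([plate_shift[p] for p in plate_of])

        rows = []
        for _, assay in plat_panel.iterrows():
            base = true_log_levels[assay["target_id"]].to_numpy().copy()
            hits = epitope[(epitope["target_id"] == assay["target_id"]) &
                           (epitope["platform"] == platform)]
            for _, ep in hits.iterrows():
                base = base + ep["effect"] * genotypes.dosage(ep["variant_id"])
            log_meas = base + shifts + rng.normal(0.0, noise_sd, size=n)
            level = np.exp(log_meas)
            lods[assay["assay_id"]] = float(
                np.quantile(level, config.lod_quantile[platform]))
            mids = [f"{platform}_{assay['assay_id']}_{d}" for d in donors]
            frame = pd.DataFrame({
                "measurement_id": mids, "donor_id": donors,
                "assay_id": assay["assay_id"], "level": level,
                "plate_id": plate_of, "is_duplicate_of": pd.NA,
            })
            if len(dup_idx):
                dup_log = base[dup_idx] + shifts[dup_idx] + \
                    rng.normal(0.0, noise_sd, size=len(dup_idx))
                dup_ids = [mids[i] + "_rep" for i in dup_idx]
                dup = pd.DataFrame({
                    "measurement_id": dup_ids,
                    "donor_id": [donors[i] for i in dup_idx],
                    "assay_id": assay["assay_id"],
                    "level": np.exp(dup_log),
                    "plate_id": plate_of[dup_idx],
                    "is_duplicate_of": [mids[i] for i in dup_idx],
                })
                frame.loc[frame["measurement_id"].isin(
                    [mids[i] for i in dup_idx]), "is_duplicate_of"] = \
                    frame.loc[frame["measurement_id"].isin(
                        [mids[i] for i in dup_idx]), "measurement_id"] + "_rep"
                frame = pd.concat([frame, dup], ignore_index=True)
            rows.append(frame)
        matrices[platform] = pd.concat(rows, ignore_index=True)

    panel = panel.copy()
    panel["lod"] = panel["assay_id"].map(lods)
    return matrices, samples, panel


# ---------------------------------------------------------------------------
# phenotypes


def sim_phenotypes(config: SimConfig, true_log_levels: pd.DataFrame,
                   ledger: TruthLedger,
                   rng: Optional[np.random.Generator] = None):
    """Liability-threshold binary phenotypes and linear quantitative traits.

    Both act on standardized true log levels, so the generative weights are
    in per-s.d. units.  The trait-hit catalogue lists, per phenotype, the
    causal variants inherited through the weighted proteins, with
    catalogue-style published p-values and effect directions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    z = (true_log_levels - true_log_levels.mean()) / true_log_levels.std(ddof=0)
    targets = list(true_log_levels.columns)
    n = len(z)
    pheno_cols: Dict[str, np.ndarray] = {}
    hit_rows = []

    def causal_variants(weights: Dict[int, float]):
        out = []
        for pi, w in weights.items():
            target = targets[pi]
            for table in (ledger.cis_effects, ledger.trans_effects):
                if len(table) == 0:
                    continue
                for _, row in table[table["target_id"] == target].iterrows():
                    out.append((row["variant_id"],
                                float(np.sign(w * row["beta"]))))
        return out

    for spec in config.phenotype_spec.get("binary", []):
        weights = {int(k): float(v) for k, v in spec["weights"].items()}
        liability = sum(w * z.iloc[:, pi].to_numpy()
                        for pi, w in weights.items()) if weights else \
            np.zeros(n)
        liability = np.asarray(liability, dtype=float) + rng.standard_normal(n)
        sd = float(np.sqrt(sum(w * w for w in weights.values()) + 1.0))
        thresh = stats.norm.isf(spec["prevalence"]) * sd
        pheno_cols[spec["name"]] = (liability > thresh).astype(int)
        ledger.phenotype_weights[spec["name"]] = {
            targets[pi]: w for pi, w in weights.items()}
        for vid, direction in causal_variants(weights):
            hit_rows.append({
                "trait_id": spec["name"], "variant_id": vid,
                "p": float(10 ** -rng.uniform(8, 30)),
                "direction": direction,
            })

    for spec in config.phenotype_spec.get("quantitative", []):
        weights = {int(k): float(v) for k, v in spec["weights"].items()}
        value = sum(w * z.iloc[:, pi].to_numpy()
                    for pi, w in weights.items()) if weights else np.zeros(n)
        value = np.asarray(value, dtype=float) + \
            rng.normal(0.0, spec.get("noise_sd", 1.0), size=n)
        pheno_cols[spec["name"]] = value
        ledger.phenotype_weights[spec["name"]] = {
            targets[pi]: w for pi, w in weights.items()}
        for vid, direction in causal_variants(weights):
            hit_rows.append({
                "trait_id": spec["name"], "variant_id": vid,
                "p": float(10 ** -rng.uniform(8, 30)),
                "direction": direction,
            })

    phenotypes = pd.DataFrame(
        {"donor_id": list(true_log_levels.index), **pheno_cols})
    trait_hits = pd.DataFrame(
        hit_rows, columns=["trait_id", "variant_id", "p", "direction"])
    return phenotypes, trait_hits


# ---------------------------------------------------------------------------
# orchestration


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run the full generator under one seed; every output is deterministic
    given the config."""
    rng = np.random.default_rng(config.seed)
    variants, genotypes, pop_freqs = sim_genotypes(config, rng)
    panel, true_levels, ledger = sim_proteome(config, variants, genotypes, rng)
    matrices, samples, panel = sim_measurements(
        config, genotypes, panel, true_levels, ledger, rng)
    phenotypes, trait_hits = sim_phenotypes(config, true_levels, ledger, rng)
    return SimulatedCohort(
        variants=variants, genotypes=genotypes, panel=panel,
        protein_matrices=matrices, samples=samples, phenotypes=phenotypes,
        trait_hits=trait_hits, config=config, pop_frequencies=pop_freqs,
        true_log_levels=true_levels, ledger=ledger)


def load_cohort(indir) -> SimulatedCohort:
    """Reassemble a cohort written by :meth:`SimulatedCohort.write`
    (without the generative ground truth, which is never re-read)."""
    import os

    from . import io as pio

    variants, genotypes = pio.read_genotypes(
        os.path.join(indir, "genotypes.dosage.tsv"))
    panel = pio.read_assay_panel(os.path.join(indir, "assay_panel.tsv"))
    matrices = {}
    for platform in sorted(panel["platform"].unique()):
        path = os.path.join(indir, f"protein_{platform}.tsv")
        if os.path.exists(path):
            matrices[platform] = pio.read_protein_matrix(path, panel)
    return SimulatedCohort(
        variants=variants, genotypes=genotypes, panel=panel,
        protein_matrices=matrices,
        samples=pio.read_table(os.path.join(indir, "samples.tsv")),
        phenotypes=pio.read_table(os.path.join(indir, "phenotypes.tsv")),
        trait_hits=pio.read_table(os.path.join(indir, "trait_hits.tsv")))
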