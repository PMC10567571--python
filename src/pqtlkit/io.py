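"""On-disk formats and in-memory containers shared by every pipeline stage.

Genotypes are accepted either as an (uncompressed or bgzipped) VCF with
per-sample dosages (``DS``) or hard genotypes (``GT``), or as a plain TSV
dosage matrix with a sidecar variant table.  Protein levels, assay panels,
sample tables and association summary statistics are TSV with documented
headers.  All coordinates are 1-based, inclusive, VCF-style; window tests
everywhere use absolute base-pair distance.  The effect allele is always
the alternate allele.

Downstream modules consume only the containers defined here and never
re-parse files.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Thresholds

__all__ = [
    "ParseError",
    "IntegrityError",
    "ValidationError",
    "InsufficientDataError",
    "GenotypeMatrix",
    "validate_variant_table",
    "validate_assay_panel",
    "validate_protein_matrix",
    "filter_variants",
    "read_genotypes",
    "write_genotypes",
    "write_vcf",
    "read_protein_matrix",
    "write_protein_matrix",
    "read_assay_panel",
    "write_assay_panel",
    "read_table",
    "write_table",
    "write_summary_stats",
    "read_summary_stats",
]


class ParseError(ValueError):
    """A record on disk could not be parsed; the message names the line."""


class IntegrityError(ValueError):
    """Cross-reference violation (duplicate ids, dangling links, ...)."""


class ValidationError(ValueError):
    """Values violate a container invariant (e.g. non-positive levels)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested estimator."""


VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref_allele", "alt_allele",
    "alt_freq", "maf", "info",
]

PANEL_COLUMNS = [
    "assay_id", "platform", "target_id", "target_chrom", "target_tss",
    "dilution_group", "lod", "panel_set", "subcellular_class",
]

PROTEIN_COLUMNS = [
    "measurement_id", "donor_id", "assay_id", "level", "plate_id",
    "is_duplicate_of",
]

SUMMARY_COLUMNS = [
    "assay_id", "variant_id", "effect_allele", "beta", "se", "p", "n",
]

DILUTION_GROUPS = ("low", "mid", "high")


class GenotypeMatrix:
    """Alternate-allele dosages, donors x variants, each value in [0, 2].

    Parameters
    ----------
    donors : sequence of donor ids (rows)
    variant_ids : sequence of variant ids (columns)
    dosages : float array of shape ``(len(donors), len(variant_ids))``
    """

    def __init__(self, donors: Sequence[str], variant_ids: Sequence[str],
                 dosages: np.ndarray):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(donors), len(variant_ids)):
            raise ValueError("dosage shape does not match donor/variant ids")
        if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
            raise ValidationError("dosages outside [0, 2]")
        self.donors = list(map(str, donors))
        self.variant_ids = list(map(str, variant_ids))
        self.dosages = dosages
        self._vindex = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._vindex) != len(self.variant_ids):
            raise IntegrityError("duplicated variant_id in genotype matrix")
        self._dindex = {d: i for i, d in enumerate(self.donors)}

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def dosage(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._vindex[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._vindex

    def subset_variants(self, variant_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(variant_ids)
        cols = [self._vindex[v] for v in ids]
        return GenotypeMatrix(self.donors, ids, self.dosages[:, cols])

    def subset_donors(self, donors: Iterable[str]) -> "GenotypeMatrix":
        ids = list(donors)
        rows = [self._dindex[d] for d in ids]
        return GenotypeMatrix(ids, self.variant_ids, self.dosages[rows, :])


def validate_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    missing = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing:
        raise ValidationError(f"variant table missing columns: {sorted(missing)}")
    if variants["variant_id"].duplicated().any():
        dup = variants.loc[variants["variant_id"].duplicated(), "variant_id"]
        raise IntegrityError(f"duplicated variant_id: {dup.iloc[0]!r}")
    if (variants["pos"] < 1).any():
        raise ValidationError("positions must be >= 1 (1-based)")
    expected_maf = np.minimum(variants["alt_freq"], 1 - variants["alt_freq"])
    if not np.allclose(variants["maf"], expected_maf, atol=1e-9):
        raise ValidationError("maf != min(alt_freq, 1 - alt_freq)")
    if ((variants["info"] < 0) | (variants["info"] > 1)).any():
        raise ValidationError("info scores must lie in [0, 1]")
    return variants


def validate_assay_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValidationError(f"assay panel missing columns: {sorted(missing)}")
    if panel["assay_id"].duplicated().any():
        raise IntegrityError("duplicated assay_id in panel")
    lod = panel["lod"].dropna()
    if (lod < 0).any():
        raise ValidationError("negative LOD in panel")
    bad = set(panel["dilution_group"]) - set(DILUTION_GROUPS)
    if bad:
        raise ValidationError(f"unknown dilution groups: {sorted(bad)}")
    return panel


def validate_protein_matrix(matrix: pd.DataFrame,
                            panel: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    missing = set(PROTEIN_COLUMNS) - set(matrix.columns)
    if missing:
        raise ValidationError(f"protein matrix missing columns: {sorted(missing)}")
    nonpos = matrix.index[matrix["level"] <= 0].tolist()
    if nonpos:
        raise ValidationError(f"non-positive levels at rows {nonpos[:10]}")
    if panel is not None:
        unknown = set(matrix["assay_id"]) - set(panel["assay_id"])
        if unknown:
            raise IntegrityError(f"assays absent from panel: {sorted(unknown)[:5]}")
    # duplicate links must be symmetric pairs of the same donor and assay
    linked = matrix.dropna(subset=["is_duplicate_of"])
    if len(linked):
        by_id = matrix.set_index("measurement_id")
        for _, row in linked.iterrows():
            other_id = row["is_duplicate_of"]
            if other_id not in by_id.index:
                raise IntegrityError(
                    f"duplicate link {row['measurement_id']}->{other_id} dangling")
            other = by_id.loc[other_id]
            if other["donor_id"] != row["donor_id"] or \
                    other["assay_id"] != row["assay_id"]:
                raise IntegrityError(
                    f"duplicate link {row['measurement_id']}->{other_id} "
                    "crosses donors or assays")
            if other["is_duplicate_of"] != row["measurement_id"]:
                raise IntegrityError(
                    f"duplicate link {row['measurement_id']}->{other_id} "
                    "not symmetric")
    return matrix


def filter_variants(variants: pd.DataFrame, dosages: np.ndarray,
                    thresholds: Thresholds):
    """Apply the MAF/info inclusion filters; idempotent."""
    keep = ((variants["maf"] > thresholds.maf_min) &
            (variants["info"] > thresholds.info_min)).to_numpy()
    return variants.loc[keep].reset_index(drop=True), dosages[:, keep]


# ---------------------------------------------------------------------------
# genotype I/O


def _read_vcf(path: str):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    rows, columns = [], []
    seen = set()
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if vid in seen:
            raise IntegrityError(f"duplicated variant_id {vid!r} in {path}")
        seen.add(vid)
        if len(rec.ALT) != 1:
            raise ParseError(f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                             "split before reading")
        ds = rec.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            gt = np.asarray(rec.gt_types)
            dose = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
            dose[gt == 2] = np.nan
        dose = np.clip(dose, 0.0, 2.0)
        af = rec.INFO.get("AF")
        if af is None:
            af = float(np.nanmean(dose)) / 2.0
        info = rec.INFO.get("R2")
        if info is None:
            info = rec.INFO.get("INFO", 1.0)
        rows.append({
            "variant_id": vid, "chrom": rec.CHROM, "pos": rec.POS,
            "ref_allele": rec.REF, "alt_allele": rec.ALT[0],
            "alt_freq": float(af), "maf": min(float(af), 1 - float(af)),
            "info": float(info),
        })
        columns.append(dose)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (np.column_stack(columns) if columns
               else np.empty((len(donors), 0)))
    return variants, donors, dosages


def _read_dosage_tsv(path: str):
    variant_path = str(path).replace(".dosage.tsv", ".variants.tsv")
    if variant_path == str(path):
        variant_path = str(path) + ".variants.tsv"
    variants = pd.read_csv(variant_path, sep="\t",
                           dtype={"variant_id": str, "chrom": str})
    wide = pd.read_csv(path, sep="\t", index_col=0)
    donors = wide.index.astype(str).tolist()
    dosages = np.clip(wide.to_numpy(dtype=float), 0.0, 2.0)
    if list(wide.columns) != list(variants["variant_id"]):
        raise IntegrityError("dosage matrix columns disagree with variant table")
    return variants, donors, dosages


def read_genotypes(path, thresholds: Optional[Thresholds] = None):
    """Read genotypes and apply the variant inclusion filters.

    Returns ``(VariantTable, GenotypeMatrix)``.  Variants failing
    ``maf > maf_min`` or ``info > info_min`` are dropped; dosages are
    clipped to [0, 2]; 1-based positions are preserved.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        variants, donors, dosages = _read_vcf(path)
    else:
        variants, donors, dosages = _read_dosage_tsv(path)
    validate_variant_table(variants)
    if thresholds is not None:
        variants, dosages = filter_variants(variants, dosages, thresholds)
    return variants, GenotypeMatrix(donors, variants["variant_id"], dosages)


def write_genotypes(variants: pd.DataFrame, genotypes: GenotypeMatrix,
                    prefix) -> str:
    """Write the TSV dosage matrix + sidecar variant table; returns the
    dosage path accepted by :func:`read_genotypes`."""
    prefix = str(prefix)
    variants.to_csv(prefix + ".variants.tsv", sep="\t", index=False,
                    float_format="%.6g")
    wide = pd.DataFrame(np.round(genotypes.dosages, 4),
                        index=pd.Index(genotypes.donors, name="donor_id"),
                        columns=genotypes.variant_ids)
    wide.to_csv(prefix + ".dosage.tsv", sep="\t", float_format="%.4f")
    return prefix + ".dosage.tsv"


def write_vcf(variants: pd.DataFrame, genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with DS dosages (for interchange and tests)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation info">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.donors) + "\n")
        order = variants.sort_values(["chrom", "pos"], kind="mergesort")
        for _, v in order.iterrows():
            dose = genotypes.dosage(v["variant_id"])
            fields = [
                str(v["chrom"]), str(int(v["pos"])), str(v["variant_id"]),
                str(v["ref_allele"]), str(v["alt_allele"]), ".", "PASS",
                f"AF={v['alt_freq']:.6g};R2={v['info']:.6g}", "DS",
            ] + [f"{d:.4f}" for d in dose]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# protein / panel / generic tables


def read_protein_matrix(path, panel: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", dtype={
        "measurement_id": str, "donor_id": str, "assay_id": str,
        "plate_id": str, "is_duplicate_of": str,
    })
    return validate_protein_matrix(matrix, panel)


def write_protein_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_assay_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={
        "assay_id": str, "platform": str, "target_id": str,
        "target_chrom": str, "panel_set": str, "subcellular_class": str,
    })
    return validate_assay_panel(panel)


def write_assay_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    """Generic TSV reader for sample/phenotype/signal tables."""
    return pd.read_csv(path, sep="\t", dtype={"donor_id": str, "plate_id": str})


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_summary_stats(results: pd.DataFrame, path) -> None:
    """Long-format association summary statistics; p in scientific notation,
    beta/se to 6 significant digits.  :func:`read_summary_stats` inverts."""
    out = results.copy()
    missing = set(SUMMARY_COLUMNS) - set(out.columns)
    if missing:
        raise ValidationError(f"summary stats missing columns: {sorted(missing)}")
    for col in ("beta", "se"):
        out[col] = out[col].map(lambda x: f"{x:.6g}")
    out["p"] = out["p"].map(lambda x: f"{x:.6e}")
    out[SUMMARY_COLUMNS + [c for c in out.columns if c not in SUMMARY_COLUMNS]] \
        .to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={
        "assay_id": str, "variant_id": str, "effect_allele": str,
    })
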