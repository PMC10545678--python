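"""File formats: GWAS summary statistics, PGS scoring files, dosages, phenotypes.

All tabular formats are plain TSV/CSV with headers. Numeric round-trips are
exact: floats are written with 17 significant digits. Coordinates are 1-based
(VCF convention) and variant identity is ``chrom:pos:allele1:allele2`` with
the allele pair sorted lexicographically, so a variant keeps its key whichever
allele a file happens to list as the effect allele.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("prskit")

FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file does not conform to the declared schema."""


def variant_key(chrom, pos, a1: str, a2: str) -> str:
    alleles = sorted((str(a1).upper(), str(a2).upper()))
    return f"{chrom}:{int(pos)}:{alleles[0]}:{alleles[1]}"


# ---------------------------------------------------------------------------
# Summary statistics

SUMSTATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "n_cases", "n_controls",
]

# case-insensitive header aliases seen across GWAS-catalog style files
_SUMSTATS_ALIASES = {
    "snp": "variant_id", "rsid": "variant_id", "rs_id": "variant_id",
    "markername": "variant_id",
    "chr": "chrom", "chromosome": "chrom",
    "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "a1": "effect_allele", "allele1": "effect_allele",
    "a2": "other_allele", "allele2": "other_allele", "reference_allele": "other_allele",
    "freq": "eaf", "effect_allele_frequency": "eaf", "maf": "eaf",
    "b": "beta", "effect": "beta",
    "stderr": "se", "standard_error": "se",
    "ncase": "n_cases", "n_case": "n_cases",
    "ncontrol": "n_controls", "n_control": "n_controls",
}


def _normalize_columns(df: pd.DataFrame, aliases: dict) -> pd.DataFrame:
    ren = {}
    for c in df.columns:
        lc = c.strip().lower()
        ren[c] = aliases.get(lc, lc)
    return df.rename(columns=ren)


def read_summary_stats(path) -> pd.DataFrame:
    """Read a per-ancestry GWAS summary-statistics table.

    Rows violating the schema invariants (se <= 0, eaf outside (0,1), empty
    alleles, duplicated variant key) are dropped; the count is logged and kept
    in ``df.attrs["n_dropped"]``. An ``ancestry_label`` column is preserved if
    present.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file")
    df = _normalize_columns(df, _SUMSTATS_ALIASES)
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    n0 = len(df)
    if n0 == 0:
        raise FormatError(f"{path}: no data rows")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)
    ok = (
        (pd.to_numeric(df["se"], errors="coerce") > 0)
        & pd.to_numeric(df["eaf"], errors="coerce").between(0, 1, inclusive="neither")
        & (df["effect_allele"].str.len() > 0) & (df["effect_allele"] != "NAN")
        & (df["other_allele"].str.len() > 0) & (df["other_allele"] != "NAN")
        & pd.to_numeric(df["beta"], errors="coerce").notna()
    )
    df = df[ok].copy()
    df["key"] = [variant_key(c, p, a, b) for c, p, a, b
                 in zip(df["chrom"], df["pos"], df["effect_allele"], df["other_allele"])]
    df = df[~df["key"].duplicated(keep="first")]
    n_dropped = n0 - len(df)
    if n_dropped:
        log.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    df = df.reset_index(drop=True)
    df.attrs["n_dropped"] = n_dropped
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c != "key"]
    df[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Weight (scoring) files — PGS-Catalog compatible column names

_WEIGHT_ALIASES = {
    "rsid": "variant_id", "snp": "variant_id",
    "chr_name": "chrom", "chr": "chrom", "chromosome": "chrom",
    "chr_position": "pos", "position": "pos", "bp": "pos",
    "allelefrequency_effect": "eaf",
    "a1": "effect_allele", "a2": "other_allele",
}

WEIGHT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "effect_weight"]


def read_weights(path) -> pd.DataFrame:
    """Read a PGS-Catalog-style scoring file (TSV, '#' comment header allowed)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file")
    df = _normalize_columns(df, _WEIGHT_ALIASES)
    for col in WEIGHT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)
    if not np.all(np.isfinite(df["effect_weight"].to_numpy(float))):
        raise FormatError(f"{path}: non-finite effect_weight")
    df["key"] = [variant_key(c, p, a, b) for c, p, a, b
                 in zip(df["chrom"], df["pos"], df["effect_allele"], df["other_allele"])]
    if df["key"].duplicated().any():
        raise FormatError(f"{path}: duplicated variant keys")
    return df.reset_index(drop=True)


def write_weights(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"variant_id": "rsID", "chrom": "chr_name",
                             "pos": "chr_position", "eaf": "allelefrequency_effect"})
    cols = [c for c in out.columns if c != "key"]
    out[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Phenotypes

PHENO_COLUMNS = ["sample_id", "study", "group_label", "age", "sex",
                 "pc1", "pc2", "pc3", "pc4", "famhx", "case"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a per-sample phenotype/covariate CSV.

    ``time``/``event`` are optional but must be present together; ``famhx``
    is one of {yes,no,missing}.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file")
    df = _normalize_columns(df, {})
    for col in PHENO_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample_id")
    has_time, has_event = "time" in df.columns, "event" in df.columns
    if has_time != has_event:
        raise FormatError(f"{path}: 'time' and 'event' must be present together")
    if has_time and (pd.to_numeric(df["time"], errors="coerce") < 0).any():
        raise FormatError(f"{path}: negative follow-up time")
    bad = set(df["famhx"].astype(str)) - {"yes", "no", "missing"}
    if bad:
        raise FormatError(f"{path}: invalid famhx values {sorted(bad)}")
    return df.reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Dosages

@dataclasses.dataclass
class DosageMatrix:
    """Sample-by-variant dosage matrix with allele metadata.

    ``dosages`` columns are variant keys; ``meta`` rows (indexed by key) carry
    chrom/pos and the counted allele (``effect_allele``: the allele the dosage
    counts copies of) plus its complement. ``skipped`` lists requested
    variants that were absent from the file.
    """
    dosages: pd.DataFrame
    meta: pd.DataFrame
    skipped: list = dataclasses.field(default_factory=list)


def read_dosages(path, variant_subset: Sequence[str] | None = None) -> DosageMatrix:
    """Read genotype dosages from a VCF (DS preferred, GT fallback) or a TSV.

    A TSV has samples in rows (first column ``sample_id``) and variant keys as
    the remaining column names. Dosages must lie in [0, 2]; missing values are
    allowed (NaN, or '.'/'./.' in VCF).
    """
    path = Path(path)
    first = open(path).readline()
    if path.suffix.lower() == ".vcf" or first.startswith("##fileformat"):
        dm = _read_vcf_dosages(path)
    else:
        dm = _read_tsv_dosages(path)
    vals = dm.dosages.to_numpy(float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise FormatError(f"{path}: dosage outside [0, 2]")
    if variant_subset is not None:
        present = [k for k in variant_subset if k in dm.dosages.columns]
        skipped = [k for k in variant_subset if k not in dm.dosages.columns]
        if skipped:
            log.warning("%s: %d requested variant(s) not found", path, len(skipped))
        dm = DosageMatrix(dm.dosages[present], dm.meta.loc[present], skipped)
    return dm


def _read_vcf_dosages(path: Path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys, rows, meta_rows = [], [], []
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        key = variant_key(v.CHROM, v.POS, v.REF, alt)
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d[d < -0.5] = np.nan  # cyvcf2 encodes missing as large negative
        else:
            gt = np.asarray(v.gt_types, dtype=float)  # 0,1,3 = hom_ref,het,hom_alt; 2 = unknown
            d = np.where(gt == 3, 2.0, gt)
            d[np.asarray(v.gt_types) == 2] = np.nan
        keys.append(key)
        rows.append(d)
        meta_rows.append((key, str(v.CHROM), int(v.POS), alt.upper(), v.REF.upper()))
    if not keys:
        raise FormatError(f"{path}: no variant records")
    dosages = pd.DataFrame(np.column_stack(rows), index=samples, columns=keys)
    dosages.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows, columns=["key", "chrom", "pos", "effect_allele", "other_allele"]).set_index("key")
    return DosageMatrix(dosages, meta)


def _read_tsv_dosages(path: Path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column of a dosage TSV must be 'sample_id'")
    df = df.set_index("sample_id")
    meta_rows = []
    for key in df.columns:
        parts = key.split(":")
        if len(parts) != 4:
            raise FormatError(f"{path}: column '{key}' is not a chrom:pos:a1:a2 variant key")
        chrom, pos, a1, a2 = parts
        # a TSV key is allele-sorted: count copies of the first allele by convention
        meta_rows.append((key, chrom, int(pos), a1.upper(), a2.upper()))
    meta = pd.DataFrame(meta_rows, columns=["key", "chrom", "pos", "effect_allele", "other_allele"]).set_index("key")
    return DosageMatrix(df.astype(float), meta)


def write_dosages_tsv(dm: DosageMatrix, path) -> None:
    out = dm.dosages.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_vcf(dm: DosageMatrix, path) -> None:
    """Write dosages as a minimal VCF with GT (rounded) and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        samples = "\t".join(str(s) for s in dm.dosages.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for key in dm.dosages.columns:
            m = dm.meta.loc[key]
            vals = dm.dosages[key].to_numpy(float)
            cells = []
            for d in vals:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map[int(round(d))]}:{d:g}")
            fh.write(f"{m['chrom']}\t{m['pos']}\t{key}\t{m['other_allele']}\t{m['effect_allele']}"
                     f"\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Run configuration and run log

@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide knobs: bootstrap replicates, landmark horizon, thresholds."""
    seed: int = 0
    n_bootstrap: int = 500
    landmark_time: float = 10.0
    risk_thresholds: tuple = (0.0029, 0.0039, 0.0049)
    pc_count: int = 4
    output_dir: str = "."

    def __post_init__(self):
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.pc_count < 1:
            raise ValueError("pc_count must be >= 1")
        for t in self.risk_thresholds:
            if not 0 < t < 1:
                raise ValueError(f"risk threshold {t} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "risk_thresholds" in raw:
            raw["risk_thresholds"] = tuple(raw["risk_thresholds"])
        return cls(**raw)


def write_run_summary(path, command: str, seed, counts: dict) -> None:
    """Machine-readable JSON audit record for one pipeline invocation."""
    summary = {
        "command": command,
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "counts": counts,
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
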