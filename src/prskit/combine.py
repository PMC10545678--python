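"""Cross-ancestry combination of GWAS summary statistics and LD matrices.

Two ancestries' marginal effect estimates are harmonized to a common effect
allele, pooled per variant by inverse-variance weighting, and their
block-diagonal LD correlation matrices blended with weights proportional to
the per-ancestry sample sizes — the inputs a genome-wide shrinkage method
(e.g. LDpred2) consumes for a single cross-ancestry PRS.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FLOAT_FMT, write_summary_stats

_PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclasses.dataclass
class LDMatrix:
    """Block-diagonal variant correlation structure for one ancestry.

    ``blocks`` is a list of ``(variant_keys, R)`` pairs with R symmetric,
    unit-diagonal, entries in [-1, 1].
    """
    blocks: list
    ancestry_label: str
    n_samples: int

    def validate(self, eig_floor: float = -1e-8) -> None:
        for i, (keys, R) in enumerate(self.blocks):
            R = np.asarray(R)
            if R.shape != (len(keys), len(keys)):
                raise ValueError(f"block {i}: shape does not match variant count")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError(f"block {i}: not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ValueError(f"block {i}: diagonal not 1")
            if np.abs(R).max() > 1 + 1e-10:
                raise ValueError(f"block {i}: off-diagonal outside [-1, 1]")
            if np.linalg.eigvalsh(R).min() < eig_floor:
                raise ValueError(f"block {i}: negative eigenvalue below floor")

    @property
    def variant_keys(self):
        return [k for keys, _ in self.blocks for k in keys]


def estimate_ld(dosages: pd.DataFrame, blocks: pd.Series, ancestry_label: str) -> LDMatrix:
    """Pearson-correlation LD per block from a dosage panel."""
    out = []
    for b in sorted(blocks.unique()):
        keys = list(blocks.index[blocks == b])
        X = dosages[keys].to_numpy(float)
        with np.errstate(invalid="ignore"):  # monomorphic columns -> NaN, zeroed below
            R = np.corrcoef(X, rowvar=False)
        R = np.atleast_2d(np.nan_to_num(R, nan=0.0))
        R = (R + R.T) / 2.0  # corrcoef is symmetric only to rounding
        np.fill_diagonal(R, 1.0)
        out.append((keys, R))
    return LDMatrix(out, ancestry_label, len(dosages))


# ---------------------------------------------------------------------------

def harmonize(ss_a: pd.DataFrame, ss_b: pd.DataFrame,
              drop_palindromic: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match two summary-statistics tables on (chrom, pos) and align alleles.

    Returns ``(harmonized, drops)``. In the harmonized table B's effect is
    expressed on A's effect allele: when B's effect allele equals A's other
    allele, B's beta is negated, its EAF replaced by 1-EAF, and
    ``flip_applied`` set. Variants present in only one table, palindromic
    variants (A/T, C/G; by default), and allele-incompatible positions are
    dropped with a reason code.
    """
    a = ss_a.copy()
    b = ss_b.copy()
    a["_locus"] = a["chrom"].astype(str) + ":" + a["pos"].astype(str)
    b["_locus"] = b["chrom"].astype(str) + ":" + b["pos"].astype(str)
    merged = a.merge(b, on="_locus", how="outer", suffixes=("_A", "_B"), indicator=True)

    drops = []
    rows = []
    for _, r in merged.iterrows():
        if r["_merge"] == "left_only":
            drops.append((r["_locus"], "missing_in_B"))
            continue
        if r["_merge"] == "right_only":
            drops.append((r["_locus"], "missing_in_A"))
            continue
        ea_a, oa_a = r["effect_allele_A"], r["other_allele_A"]
        ea_b, oa_b = r["effect_allele_B"], r["other_allele_B"]
        if drop_palindromic and {ea_a, oa_a} in _PALINDROMIC:
            drops.append((r["_locus"], "palindromic"))
            continue
        if (ea_b, oa_b) == (ea_a, oa_a):
            flip = False
            beta_b, eaf_b = r["beta_B"], r["eaf_B"]
        elif (ea_b, oa_b) == (oa_a, ea_a):
            flip = True
            beta_b, eaf_b = -r["beta_B"], 1.0 - r["eaf_B"]
        else:
            drops.append((r["_locus"], "allele_mismatch"))
            continue
        rows.append({
            "key": r["key_A"], "chrom": r["chrom_A"], "pos": r["pos_A"],
            "effect_allele": ea_a, "other_allele": oa_a,
            "variant_id": r["variant_id_A"],
            "beta_A": r["beta_A"], "se_A": r["se_A"], "eaf_A": r["eaf_A"],
            "n_cases_A": r["n_cases_A"], "n_controls_A": r["n_controls_A"],
            "beta_B": beta_b, "se_B": r["se_B"], "eaf_B": eaf_b,
            "n_cases_B": r["n_cases_B"], "n_controls_B": r["n_controls_B"],
            "flip_applied": flip,
        })
    harmonized = pd.DataFrame(rows)
    drops_df = pd.DataFrame(drops, columns=["locus", "reason"])
    return harmonized, drops_df


def ivw_meta(beta_a, se_a, beta_b, se_b):
    """Inverse-variance-weighted fixed-effect combination of two estimates.

    ``beta = (w_a*beta_a + w_b*beta_b) / (w_a + w_b)`` with ``w = 1/se**2``;
    ``se = 1/sqrt(w_a + w_b)``. Vectorized over arrays.
    """
    beta_a, se_a = np.asarray(beta_a, float), np.asarray(se_a, float)
    beta_b, se_b = np.asarray(beta_b, float), np.asarray(se_b, float)
    for arr, name in ((beta_a, "beta_a"), (beta_b, "beta_b")):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name}")
    if np.any(se_a <= 0) or np.any(se_b <= 0):
        raise ValueError("standard errors must be positive")
    w_a, w_b = 1.0 / se_a**2, 1.0 / se_b**2
    beta = (w_a * beta_a + w_b * beta_b) / (w_a + w_b)
    se = 1.0 / np.sqrt(w_a + w_b)
    return beta, se


def blend_ld(ld_a: LDMatrix, ld_b: LDMatrix, n_a: int, n_b: int) -> LDMatrix:
    """Sample-size-weighted blend of two same-structured LD matrices.

    Each block becomes ``(n_a*R_A + n_b*R_B) / (n_a + n_b)``; a convex
    combination of correlation matrices, so symmetry, the unit diagonal and
    positive semidefiniteness are preserved.
    """
    if n_a < 0 or n_b < 0 or n_a + n_b == 0:
        raise ValueError("sample sizes must be non-negative and not both zero")
    if len(ld_a.blocks) != len(ld_b.blocks):
        raise ValueError("block counts differ")
    out = []
    for i, ((keys_a, R_a), (keys_b, R_b)) in enumerate(zip(ld_a.blocks, ld_b.blocks)):
        if list(keys_a) != list(keys_b):
            raise ValueError(f"block {i}: variant keys differ between ancestries")
        R = (n_a * np.asarray(R_a, float) + n_b * np.asarray(R_b, float)) / (n_a + n_b)
        out.append((list(keys_a), R))
    return LDMatrix(out, "combined", n_a + n_b)


def combine_summary_stats(harmonized: pd.DataFrame) -> pd.DataFrame:
    """IVW-pooled summary statistics from a harmonized pair.

    EAF is the total-sample-size-weighted average of the two ancestries' EAFs;
    case/control counts are summed.
    """
    if len(harmonized) == 0:
        raise ValueError("no shared variants")
    beta, se = ivw_meta(harmonized["beta_A"], harmonized["se_A"],
                        harmonized["beta_B"], harmonized["se_B"])
    n_a = harmonized["n_cases_A"] + harmonized["n_controls_A"]
    n_b = harmonized["n_cases_B"] + harmonized["n_controls_B"]
    eaf = (n_a * harmonized["eaf_A"] + n_b * harmonized["eaf_B"]) / (n_a + n_b)
    out = pd.DataFrame({
        "variant_id": harmonized["variant_id"],
        "chrom": harmonized["chrom"],
        "pos": harmonized["pos"],
        "effect_allele": harmonized["effect_allele"],
        "other_allele": harmonized["other_allele"],
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "n_cases": (harmonized["n_cases_A"] + harmonized["n_cases_B"]).astype(int),
        "n_controls": (harmonized["n_controls_A"] + harmonized["n_controls_B"]).astype(int),
        "ancestry_label": "combined",
    })
    out["key"] = harmonized["key"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# LD serialization: long TSV (block, key_i, key_j, r), upper triangle incl. diagonal

def write_ld_blocks(ld: LDMatrix, path) -> None:
    rows = []
    for b, (keys, R) in enumerate(ld.blocks):
        R = np.asarray(R)
        for i in range(len(keys)):
            for j in range(i, len(keys)):
                rows.append((b, keys[i], keys[j], R[i, j]))
    df = pd.DataFrame(rows, columns=["block", "key_i", "key_j", "r"])
    df.attrs = {}
    header = f"#ancestry={ld.ancestry_label}\tn_samples={ld.n_samples}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ld_blocks(path) -> LDMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(kv.split("=", 1) for kv in header.lstrip("#").split("\t"))
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    blocks = []
    for b in sorted(df["block"].unique()):
        sub = df[df["block"] == b]
        keys = list(dict.fromkeys(list(sub["key_i"]) + list(sub["key_j"])))
        idx = {k: i for i, k in enumerate(keys)}
        R = np.eye(len(keys))
        for _, r in sub.iterrows():
            i, j = idx[r["key_i"]], idx[r["key_j"]]
            R[i, j] = R[j, i] = r["r"]
        blocks.append((keys, R))
    return LDMatrix(blocks, fields.get("ancestry", "unknown"),
                    int(fields.get("n_samples", 0)))


def export_ldpred_inputs(harmonized: pd.DataFrame, blended_ld: LDMatrix, out_dir) -> dict:
    """Write the combined summary statistics and blended LD blocks.

    Returns the paths written. The combined file pools case/control counts
    across ancestries and carries IVW effect estimates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    combined = combine_summary_stats(harmonized)
    ss_path = out_dir / "combined_sumstats.tsv"
    ld_path = out_dir / "combined_ld.tsv"
    write_summary_stats(combined, ss_path)
    write_ld_blocks(blended_ld, ld_path)
    return {"sumstats": str(ss_path), "ld": str(ld_path)}
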