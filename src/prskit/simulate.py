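"""Synthetic reference panels, GWAS summary statistics, and validation cohorts.

The generators reproduce the statistical structure the downstream analysis
assumes, at desk scale:

* two ancestral groups whose allele frequencies drift apart under a
  Balding–Nichols model, with block-exchangeable LD induced by a Gaussian
  copula on haplotypes;
* per-ancestry marginal GWAS effects equal to the LD-block rotation of the
  true effects plus sampling noise at the standard case-control SE,
  ``se = sqrt(1 / (2 f (1-f) n_eff))`` with ``n_eff = 4/(1/n_cases + 1/n_controls)``;
* individual-level cohorts with a log-linear PRS->risk relationship, a
  family-history covariate, exponential cause-specific CRC and death hazards,
  and administrative censoring at the end of follow-up.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import variant_key

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"),
                 ("C", "A"), ("G", "T"), ("C", "T"), ("A", "T"), ("C", "G")]


@dataclasses.dataclass
class SimPanel:
    """Reference panel: integer dosages, ancestry labels, frequencies, LD blocks."""
    dosages: pd.DataFrame          # samples x variant keys, values in {0,1,2}
    ancestry: pd.Series            # per-sample ancestry label
    freqs: pd.DataFrame            # generating allele frequency, ancestry x key
    blocks: pd.Series              # key -> block index
    meta: pd.DataFrame             # key -> chrom, pos, effect_allele, other_allele

    @property
    def variant_keys(self):
        return list(self.dosages.columns)

    def ancestry_dosages(self, label: str) -> pd.DataFrame:
        return self.dosages.loc[self.ancestry[self.ancestry == label].index]


@dataclasses.dataclass
class SimTruth:
    """Ground truth of the simulation.

    ``baseline_risk_10yr`` is the 10-year cumulative incidence of CRC for a
    baseline individual (PRS = 0, no family history) in the presence of the
    competing death hazard; the baseline CRC hazard is solved from it.
    """
    variant_effects: dict | None = None        # key -> true log-OR
    beta_prs: float = float(np.log(1.67))      # per-SD log-OR of the PRS
    baseline_risk_10yr: float = 0.003
    famhx_log_or: float = float(np.log(2.0))
    famhx_prevalence: float = 0.09
    death_hazard: float = 0.003                # per year
    censoring_rate: float = 0.0                # per year, on top of admin censoring
    landmark_time: float = 10.0
    baseline_hazard_override: float | None = None  # bypass the risk-based solve

    def __post_init__(self):
        if not 0 < self.baseline_risk_10yr < 1:
            raise ValueError("baseline_risk_10yr must lie in (0, 1)")
        for name in ("beta_prs", "famhx_log_or", "death_hazard", "censoring_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def baseline_hazard(self) -> float:
        """CRC cause-specific hazard solving CIF(landmark) = baseline_risk_10yr."""
        if self.baseline_hazard_override is not None:
            return float(self.baseline_hazard_override)
        p, lam2, t = self.baseline_risk_10yr, self.death_hazard, self.landmark_time

        def f(lam1):
            return cif_two_exponential(lam1, lam2, t) - p

        return float(optimize.brentq(f, 1e-12, 10.0))

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def cif_two_exponential(lam1: float, lam2: float, t: float) -> float:
    """Closed-form cause-1 cumulative incidence of two independent exponentials."""
    tot = lam1 + lam2
    if tot == 0:
        return 0.0
    return lam1 / tot * -np.expm1(-tot * t)


# ---------------------------------------------------------------------------

def simulate_panel(n_per_ancestry: int, m_variants: int, n_blocks: int,
                   divergence: float, seed: int, block_rho: float = 0.5,
                   ancestries=("ASN", "EUR")) -> SimPanel:
    """Simulate a two-ancestry diploid reference panel with block LD.

    Ancestral allele frequencies are uniform on (0.05, 0.95); each ancestry's
    frequencies drift by a Balding–Nichols Beta draw with fixation index
    ``divergence`` (0 = no drift). Within a block, haplotype alleles share an
    exchangeable Gaussian-copula correlation ``block_rho``.
    """
    if not 0 <= divergence <= 0.5:
        raise ValueError("divergence must lie in [0, 0.5]")
    if m_variants < n_blocks:
        raise ValueError("m_variants must be >= n_blocks")
    rng = np.random.default_rng(seed)

    p_anc = rng.uniform(0.05, 0.95, size=m_variants)
    freqs = {}
    for a in ancestries:
        if divergence == 0:
            freqs[a] = p_anc.copy()
        else:
            F = divergence
            alpha = p_anc * (1 - F) / F
            beta = (1 - p_anc) * (1 - F) / F
            freqs[a] = np.clip(rng.beta(alpha, beta), 1e-4, 1 - 1e-4)

    pairs = [_ALLELE_PAIRS[int(i)] for i in rng.integers(0, len(_ALLELE_PAIRS), m_variants)]
    keys, meta_rows = [], []
    for j, (alt, ref) in enumerate(pairs):
        pos = (j + 1) * 1000
        key = variant_key("1", pos, alt, ref)
        keys.append(key)
        meta_rows.append((key, "1", pos, alt, ref))
    meta = pd.DataFrame(meta_rows, columns=["key", "chrom", "pos", "effect_allele",
                                            "other_allele"]).set_index("key")

    block_of = np.repeat(np.arange(n_blocks), int(np.ceil(m_variants / n_blocks)))[:m_variants]
    blocks = pd.Series(block_of, index=keys)

    sample_ids, labels, rows = [], [], []
    for a in ancestries:
        thr = stats.norm.ppf(freqs[a])
        geno = np.zeros((n_per_ancestry, m_variants), dtype=np.int8)
        for _hap in range(2):
            z = np.empty((n_per_ancestry, m_variants))
            for b in range(n_blocks):
                idx = np.where(block_of == b)[0]
                w = rng.standard_normal((n_per_ancestry, 1))
                e = rng.standard_normal((n_per_ancestry, idx.size))
                z[:, idx] = np.sqrt(block_rho) * w + np.sqrt(1 - block_rho) * e
            geno += (z < thr)
        rows.append(geno)
        sample_ids += [f"{a}_{i}" for i in range(n_per_ancestry)]
        labels += [a] * n_per_ancestry
    dosages = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=keys)
    dosages.index.name = "sample_id"
    ancestry = pd.Series(labels, index=sample_ids, name="ancestry")
    freq_df = pd.DataFrame(freqs, index=keys).T
    return SimPanel(dosages, ancestry, freq_df, blocks, meta)


def simulate_gwas(panel: SimPanel, truth: SimTruth, n_cases: int, n_controls: int,
                  ancestry: str, seed: int) -> pd.DataFrame:
    """Simulate marginal GWAS summary statistics for one ancestry.

    The expected marginal effect of each variant is the within-block LD
    rotation (empirical genotype correlation of this ancestry's panel) applied
    to the true effects; observed effects add independent Gaussian noise at
    the plug-in case-control SE. Monomorphic variants are excluded.
    """
    if truth.variant_effects is None:
        raise ValueError("truth.variant_effects is not set")
    rng = np.random.default_rng(seed)
    dos = panel.ancestry_dosages(ancestry)
    keys = panel.variant_keys
    beta_true = np.array([truth.variant_effects.get(k, 0.0) for k in keys])

    marginal = np.zeros(len(keys))
    block_of = panel.blocks.to_numpy()
    X = dos.to_numpy(float)
    for b in np.unique(block_of):
        idx = np.where(block_of == b)[0]
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(X[:, idx], rowvar=False)
        R = np.atleast_2d(np.nan_to_num(R, nan=0.0))
        np.fill_diagonal(R, 1.0)
        marginal[idx] = R @ beta_true[idx]

    f = X.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    if not poly.all():
        import logging
        logging.getLogger("prskit").warning("excluding %d monomorphic variant(s)",
                                            int((~poly).sum()))
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    se = np.sqrt(1.0 / (2.0 * f[poly] * (1.0 - f[poly]) * n_eff))
    beta_hat = marginal[poly] + rng.standard_normal(poly.sum()) * se

    kept = [k for k, ok in zip(keys, poly) if ok]
    m = panel.meta.loc[kept]
    out = pd.DataFrame({
        "variant_id": kept,
        "chrom": m["chrom"].to_numpy(),
        "pos": m["pos"].to_numpy(),
        "effect_allele": m["effect_allele"].to_numpy(),
        "other_allele": m["other_allele"].to_numpy(),
        "eaf": f[poly],
        "beta": beta_hat,
        "se": se,
        "n_cases": n_cases,
        "n_controls": n_controls,
        "ancestry_label": ancestry,
    })
    out["key"] = kept
    return out


def simulate_cohort(truth: SimTruth, n: int, group_mix: dict, follow_up_years: float,
                    seed: int, study: str = "SIM", age_range=(40, 79),
                    famhx_missing_frac: float = 0.0,
                    prs_group_shift: dict | None = None) -> pd.DataFrame:
    """Simulate an individual-level validation cohort with follow-up.

    PRS is standard normal within each group (plus an optional per-group mean
    shift emulating unadjusted ancestry offsets). CRC and death times are
    independent exponentials; the CRC hazard is ``lam0 * exp(beta_prs*PRS +
    famhx_log_or*famhx)``. ``case`` is 1 iff CRC occurred during follow-up.
    """
    fr = np.array(list(group_mix.values()), dtype=float)
    if abs(fr.sum() - 1.0) > 1e-8:
        raise ValueError("group_mix fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups = rng.choice(list(group_mix.keys()), size=n, p=fr / fr.sum())
    shift = np.zeros(n)
    if prs_group_shift:
        shift = np.array([prs_group_shift.get(g, 0.0) for g in groups])
    prs = rng.standard_normal(n) + shift

    famhx_num = rng.binomial(1, truth.famhx_prevalence, size=n)
    famhx = np.where(famhx_num == 1, "yes", "no").astype(object)
    if famhx_missing_frac > 0:
        miss = rng.random(n) < famhx_missing_frac
        famhx[miss] = "missing"

    lam0 = truth.baseline_hazard
    lam1 = lam0 * np.exp(truth.beta_prs * (prs - shift) + truth.famhx_log_or * famhx_num)
    with np.errstate(divide="ignore"):
        t_crc = rng.exponential(1.0, size=n) / lam1
        t_death = (rng.exponential(1.0 / truth.death_hazard, size=n)
                   if truth.death_hazard > 0 else np.full(n, np.inf))
        t_cens = (rng.exponential(1.0 / truth.censoring_rate, size=n)
                  if truth.censoring_rate > 0 else np.full(n, np.inf))
    t_admin = float(follow_up_years)
    time = np.minimum.reduce([t_crc, t_death, t_cens, np.full(n, t_admin)])
    event = np.zeros(n, dtype=int)
    event[time == t_crc] = 1
    event[(time == t_death) & (event == 0)] = 2

    out = pd.DataFrame({
        "sample_id": [f"{study}_{i}" for i in range(n)],
        "study": study,
        "group_label": groups,
        "age": rng.integers(age_range[0], age_range[1] + 1, size=n),
        "sex": rng.binomial(1, 0.5, size=n),
        "pc1": rng.standard_normal(n),
        "pc2": rng.standard_normal(n),
        "pc3": rng.standard_normal(n),
        "pc4": rng.standard_normal(n),
        "famhx": famhx,
        "case": (event == 1).astype(int),
        "time": time,
        "event": event,
        "prs": prs,
    })
    return out
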