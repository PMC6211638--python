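"""Synthetic data generator for biallelic reporter and binding assays.

The generator emulates the statistical structure the downstream analysis
assumes: a biallelic oligo library (two alleles x two orientations per SNP,
200 bp regulatory insert with the SNP centered, 15 bp adapter flanks on a
230 bp synthesized insert), plasmid-library allele imbalance, overdispersed
RNA molecule counts with true allelic effects on the log-odds scale, PCR
duplication tagged by UMIs, and bound/unbound binding fractions with
allele-specific affinity shifts.  Every draw is deterministic given the
config seed, and a ground-truth table is emitted alongside the data so
recovery can be tested.

Model summary
-------------
* Library imbalance: the plasmid reference proportion for SNP *i* is
  ``p_dna ~ Beta(c, c)`` with ``c = lib_imbalance_conc`` (``c -> inf`` gives
  an exactly balanced library).
* ASE: a fraction ``pi_functional`` of SNPs carry a true effect
  ``beta ~ N(0, tau_beta^2)`` on the log-odds of the reference allele in
  RNA; the rest have ``beta = 0`` exactly.
* Overdispersion: per (SNP, replicate) the realized reference proportion is
  drawn from a Beta distribution with mean ``expit(logit(p_dna) + beta)``
  and correlation parameter ``rho_true``; molecule counts are binomial given
  that draw, so pooled counts are beta-binomial with variance inflation
  ``1 + (N - 1) * rho_true``.
* PCR duplication: each RNA molecule receives a UMI uniform over
  ``4**umi_length`` and is emitted ``1 + Poisson(mu_dup * A)`` times, where
  ``A`` is a lognormal amplification propensity attached to the (SNP,
  allele) fragment and shared across replicates -- amplification efficiency
  is a property of the fragment sequence, which is what makes retained
  duplicates inflate replicate-combined statistics rather than cancel.
* Binding: the unbound fraction keeps the library proportion; the bound
  fraction shifts it by ``gamma * conc_scale`` on the log-odds scale, with a
  per-concentration scale factor.  Region-level bound totals are scaled by
  ``2**region_logfc_true`` (footprint regions get a higher mean).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import ConfigError

ORIENTATIONS = ("forward", "reverse")
CONCENTRATIONS = ("low", "mid", "high")
CATEGORIES = ("eQTL", "CentiSNP", "GWAS", "negative_control")

# Oligo design constants: 230 bp synthesized insert = 200 bp of regulatory
# sequence (SNP centered) plus 15 bp adapter flanks matching the sequencing
# primers.
INSERT_LENGTH_BP = 230
REGULATORY_LENGTH_BP = 200
ADAPTER_FLANK_BP = 15

_BASES = np.array(["A", "C", "G", "T"])

# independent RNG streams per stage so adding draws to one stage does not
# perturb another
_STREAM_DESIGN = 0
_STREAM_DNA = 1
_STREAM_RNA = 2
_STREAM_MOLECULES = 3
_STREAM_BINDING = 4
_STREAM_FASTA = 5


@dataclasses.dataclass
class SimConfig:
    """Parameters of the data-generating model.

    Defaults mirror the assay's replicate structure: nine biological RNA
    replicates, seven DNA library replicates, and binding triplicates at
    each of three factor concentrations.
    """

    n_snps: int
    pi_functional: float = 0.2
    tau_beta: float = 0.5
    pi_asb: float = 0.2
    tau_gamma: float = 0.5
    rho_true: float = 0.02
    dna_depth_mean: float = 100.0
    rna_depth_mean: float = 100.0
    fraction_depth_mean: float = 100.0
    nb_size: float = 10.0
    lib_imbalance_conc: float = 20.0
    mu_dup: float = 1.0
    dup_jackpot_sd: float = 0.3
    umi_length: int = 10
    n_rna_reps: int = 9
    n_dna_reps: int = 7
    n_bind_reps: int = 3
    n_concentrations: int = 3
    conc_gamma_scales: Sequence[float] = (0.7, 1.0, 1.1)
    frac_footprint: float = 0.3
    region_logfc_mean_fp: float = 2.0
    region_logfc_mean_bg: float = 0.0
    region_logfc_sd: float = 0.25
    centisnp_or: float = 2.5
    centisnp_base_rate: float = 0.25
    negative_control_rate: float = 0.15
    motif_factors: Sequence[str] = (
        "CTCF",
        "NFKB1",
        "E2F4",
        "CREB1",
        "RUNX1",
        "STAT1",
    )
    motif_rate: float = 0.6
    direction_specific_factor: Optional[str] = None
    corr_functional: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _check(cond: bool, field: str, msg: str) -> None:
            if not cond:
                raise ConfigError(f"{field}: {msg}")

        _check(int(self.n_snps) >= 1, "n_snps", "must be a positive integer")
        for f in (
            "pi_functional",
            "pi_asb",
            "frac_footprint",
            "centisnp_base_rate",
            "negative_control_rate",
            "motif_rate",
        ):
            v = getattr(self, f)
            _check(0.0 <= v <= 1.0, f, "must be a fraction in [0, 1]")
        _check(0.0 <= self.rho_true < 0.5, "rho_true", "must be in [0, 0.5)")
        for f in ("dna_depth_mean", "rna_depth_mean", "fraction_depth_mean"):
            _check(getattr(self, f) > 0, f, "must be > 0")
        _check(self.nb_size > 0, "nb_size", "must be > 0 (inf = Poisson)")
        _check(
            self.lib_imbalance_conc > 0,
            "lib_imbalance_conc",
            "must be > 0 (inf = exactly balanced library)",
        )
        _check(self.mu_dup >= 0, "mu_dup", "must be >= 0")
        _check(self.dup_jackpot_sd >= 0, "dup_jackpot_sd", "must be >= 0")
        _check(int(self.umi_length) >= 1, "umi_length", "must be >= 1")
        for f in ("n_rna_reps", "n_dna_reps", "n_bind_reps"):
            _check(int(getattr(self, f)) >= 1, f, "must be >= 1")
        _check(
            1 <= int(self.n_concentrations) <= len(CONCENTRATIONS),
            "n_concentrations",
            f"must be in [1, {len(CONCENTRATIONS)}]",
        )
        _check(
            len(self.conc_gamma_scales) >= int(self.n_concentrations),
            "conc_gamma_scales",
            "needs one scale per concentration",
        )
        for f in ("tau_beta", "tau_gamma", "region_logfc_sd"):
            _check(getattr(self, f) >= 0, f, "must be >= 0")
        _check(self.centisnp_or > 0, "centisnp_or", "must be > 0")
        _check(
            -1.0 <= self.corr_functional <= 1.0,
            "corr_functional",
            "must be in [-1, 1]",
        )
        _check(0 < self.centisnp_base_rate < 1, "centisnp_base_rate", "must be in (0, 1)")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _nb_draws(
    rng: np.random.Generator, mean: float, size_param: float, shape
) -> np.ndarray:
    """Negative-binomial totals with the given mean and size (inf = Poisson)."""
    if math.isinf(size_param):
        return rng.poisson(mean, size=shape)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


def _beta_mix(
    rng: np.random.Generator, mean: np.ndarray, rho: float
) -> np.ndarray:
    """Draw proportions from Beta with the given mean and correlation rho.

    Parameterization a = mean * (1 - rho) / rho, b = (1 - mean) * (1 - rho) / rho
    gives Var = mean (1 - mean) rho, hence binomial counts mixed over this
    draw have variance inflation 1 + (N - 1) rho.  rho = 0 returns the mean.
    """
    if rho == 0:
        return np.broadcast_to(mean, mean.shape).copy()
    scale = (1.0 - rho) / rho
    return rng.beta(mean * scale, (1.0 - mean) * scale)


def simulate_design(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the oligo library design and its ground-truth table.

    Returns ``(designs, truth)``.  ``designs`` has one row per SNP with the
    library annotations (category, motif factor/strand, footprint flag);
    ``truth`` carries the simulator's latent parameters per SNP (true ASE
    and binding effects on the log-odds scale, the plasmid reference
    proportion, and the region-level log2 occupancy effect).

    Guarantees: ``negative_control`` SNPs have beta_true = gamma_true = 0;
    the CentiSNP label is positively associated with beta_true != 0 at odds
    ratio ``config.centisnp_or``; deterministic given the seed.
    """
    rng = _rng(config, _STREAM_DESIGN)
    n = int(config.n_snps)
    width = max(6, len(str(n)))
    snp_id = np.array([f"snp{i:0{width}d}" for i in range(n)])
    region_id = np.array([f"reg{i:0{width}d}" for i in range(n)])

    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4

    # Gaussian copula couples the ASE-functional and ASB-functional
    # indicators at corr_functional (used for the ASE x ASB overlap checks).
    r = float(config.corr_functional)
    u1 = rng.standard_normal(n)
    u2 = r * u1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    func_ase = u1 < norm.ppf(config.pi_functional) if config.pi_functional > 0 else np.zeros(n, bool)
    func_asb = u2 < norm.ppf(config.pi_asb) if config.pi_asb > 0 else np.zeros(n, bool)

    g1 = rng.standard_normal(n)
    g2 = r * g1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    beta_true = np.where(func_ase, config.tau_beta * g1, 0.0)
    gamma_true = np.where(func_asb, config.tau_gamma * g2, 0.0)

    # CentiSNP label associated with beta_true != 0 at the configured odds
    # ratio: odds(functional) = OR * odds(background).
    odds_bg = config.centisnp_base_rate / (1.0 - config.centisnp_base_rate)
    p_func = (config.centisnp_or * odds_bg) / (1.0 + config.centisnp_or * odds_bg)
    p_centi = np.where(beta_true != 0.0, p_func, config.centisnp_base_rate)
    centi = rng.random(n) < p_centi

    category = np.full(n, "eQTL", dtype=object)
    category[centi] = "CentiSNP"
    eligible_nc = (~centi) & (beta_true == 0.0) & (gamma_true == 0.0)
    nc = eligible_nc & (rng.random(n) < config.negative_control_rate)
    category[nc] = "negative_control"
    gwas = (~centi) & (~nc) & (rng.random(n) < 0.5)
    category[gwas] = "GWAS"

    has_motif = rng.random(n) < config.motif_rate
    factor_pick = rng.integers(0, len(config.motif_factors), n)
    motif_factor = np.where(
        has_motif, np.asarray(config.motif_factors, dtype=object)[factor_pick], ""
    )
    motif_strand = np.where(has_motif, np.where(rng.random(n) < 0.5, "+", "-"), "")

    has_fp = rng.random(n) < config.frac_footprint

    if math.isinf(config.lib_imbalance_conc):
        p_dna_true = np.full(n, 0.5)
    else:
        c = config.lib_imbalance_conc
        p_dna_true = np.clip(rng.beta(c, c, n), 1e-6, 1.0 - 1e-6)

    region_logfc_true = rng.normal(
        np.where(has_fp, config.region_logfc_mean_fp, config.region_logfc_mean_bg),
        config.region_logfc_sd,
    )

    designs = pd.DataFrame(
        {
            "snp_id": snp_id,
            "region_id": region_id,
            "ref_allele": _BASES[ref_idx],
            "alt_allele": _BASES[alt_idx],
            "oligo_orientations": ",".join(ORIENTATIONS),
            "motif_factor": motif_factor,
            "motif_strand": motif_strand,
            "category": category,
            "has_target_footprint": has_fp,
        }
    )
    designs.attrs.update(
        insert_length_bp=INSERT_LENGTH_BP,
        regulatory_length_bp=REGULATORY_LENGTH_BP,
        adapter_flank_bp=ADAPTER_FLANK_BP,
    )
    truth = pd.DataFrame(
        {
            "snp_id": snp_id,
            "beta_true": beta_true,
            "gamma_true": gamma_true,
            "p_dna_true": p_dna_true,
            "region_logfc_true": region_logfc_true,
        }
    )
    return designs, truth


def _check_truth_covers(designs: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    merged = designs[["snp_id", "motif_factor", "motif_strand"]].merge(
        truth, on="snp_id", how="left", validate="one_to_one"
    )
    if merged["beta_true"].isna().any():
        missing = merged.loc[merged["beta_true"].isna(), "snp_id"].iloc[0]
        raise ConfigError(f"truth table does not cover design SNP {missing!r}")
    return merged


def orientation_betas(
    designs: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Effective ASE effect per (SNP, orientation).

    By default both orientations share beta_true.  If
    ``config.direction_specific_factor`` is set, SNPs in that factor's motif
    express their effect only when the oligo's transcription direction is
    *opposite* to the motif strand (the CTCF-style direction finding);
    "match" means motif strand '+' with a forward oligo or '-' with a
    reverse oligo.
    """
    merged = _check_truth_covers(designs, truth)
    rows = []
    for orient in ORIENTATIONS:
        beta = merged["beta_true"].to_numpy().copy()
        if config.direction_specific_factor is not None:
            in_factor = merged["motif_factor"].to_numpy() == config.direction_specific_factor
            matches = (merged["motif_strand"].to_numpy() == "+") == (orient == "forward")
            beta[in_factor & matches] = 0.0
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": merged["snp_id"],
                    "orientation": orient,
                    "beta_eff": beta,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_dna_counts(
    designs: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Plasmid DNA library allele counts: SNP x DNA replicate.

    Totals are NegBin(dna_depth_mean, nb_size); reference counts are
    binomial at the library proportion p_dna_true (no overdispersion beyond
    the library imbalance itself, matching a well-mixed plasmid pool).
    """
    merged = _check_truth_covers(designs, truth)
    rng = _rng(config, _STREAM_DNA)
    n = len(merged)
    reps = int(config.n_dna_reps)
    totals = _nb_draws(rng, config.dna_depth_mean, config.nb_size, (n, reps))
    p = merged["p_dna_true"].to_numpy()[:, None]
    ref = rng.binomial(totals, np.broadcast_to(p, totals.shape))
    out = pd.DataFrame(
        {
            "snp_id": np.repeat(merged["snp_id"].to_numpy(), reps),
            "orientation": "pooled",
            "replicate": np.tile(np.arange(1, reps + 1), n),
            "fraction": "DNA",
            "ref_count": ref.ravel(),
            "alt_count": (totals - ref).ravel(),
        }
    )
    return out


def _rna_orientation_proportions(
    merged: pd.DataFrame, designs: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ob = orientation_betas(designs, truth, config)
    bf = ob.loc[ob["orientation"] == "forward"].set_index("snp_id")["beta_eff"]
    br = ob.loc[ob["orientation"] == "reverse"].set_index("snp_id")["beta_eff"]
    bf = bf.reindex(merged["snp_id"]).to_numpy()
    br = br.reindex(merged["snp_id"]).to_numpy()
    lp = logit(merged["p_dna_true"].to_numpy())
    return expit(lp + bf), expit(lp + br), bf == br


def simulate_rna_counts(
    designs: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Deduplicated RNA molecule counts per SNP x orientation x replicate.

    Fast path that skips UMI/duplicate bookkeeping (equivalent to the
    molecule-level simulation followed by a perfect dedup).  The per-
    replicate Beta overdispersion draw is shared between the two
    orientations whenever their effects coincide, so counts are exactly
    beta-binomial with parameter rho_true at every aggregation level.
    """
    merged = _check_truth_covers(designs, truth)
    rng = _rng(config, _STREAM_RNA)
    n = len(merged)
    reps = int(config.n_rna_reps)
    p_f, p_r, same = _rna_orientation_proportions(merged, designs, truth, config)

    totals = _nb_draws(rng, config.rna_depth_mean, config.nb_size, (n, reps))
    n_fwd = rng.binomial(totals, 0.5)
    n_rev = totals - n_fwd

    pf_draw = _beta_mix(rng, np.broadcast_to(p_f[:, None], (n, reps)), config.rho_true)
    pr_indep = _beta_mix(rng, np.broadcast_to(p_r[:, None], (n, reps)), config.rho_true)
    pr_draw = np.where(same[:, None], pf_draw, pr_indep)

    r_fwd = rng.binomial(n_fwd, pf_draw)
    r_rev = rng.binomial(n_rev, pr_draw)

    rep_axis = np.tile(np.arange(1, reps + 1), n)
    snp_axis = np.repeat(merged["snp_id"].to_numpy(), reps)
    frames = []
    for orient, tot, ref in (("forward", n_fwd, r_fwd), ("reverse", n_rev, r_rev)):
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": snp_axis,
                    "orientation": orient,
                    "replicate": rep_axis,
                    "fraction": "RNA",
                    "ref_count": ref.ravel(),
                    "alt_count": (tot - ref).ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_rna_molecules(
    designs: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Read-level RNA molecule records with UMIs and PCR duplicates.

    Molecule counts are drawn exactly as in :func:`simulate_rna_counts`;
    each molecule then receives a UMI uniform over ``4**umi_length``
    (collisions allowed) and is emitted ``1 + Poisson(mu_dup * A)`` times,
    where the amplification propensity ``A ~ Lognormal(-sd^2/2, sd)`` is
    attached to the (SNP, allele) fragment and shared across replicates.
    The ``umi`` column holds integer codes; use
    :func:`allelic.io.decode_umis` for ACGT strings.
    """
    counts = simulate_rna_counts(designs, truth, config)
    rng = _rng(config, _STREAM_MOLECULES)

    snp_cat = pd.Categorical(counts["snp_id"])
    snp_codes = snp_cat.codes.astype(np.int64)
    orient_is_rev = (counts["orientation"] == "reverse").to_numpy()
    rep = counts["replicate"].to_numpy()

    r = counts["ref_count"].to_numpy(np.int64)
    a = counts["alt_count"].to_numpy(np.int64)
    tot = r + a
    total_mols = int(tot.sum())

    row_idx = np.repeat(np.arange(len(counts)), tot)
    starts = np.concatenate([[0], np.cumsum(tot)[:-1]])
    pos_in_row = np.arange(total_mols) - starts[row_idx]
    is_ref = pos_in_row < r[row_idx]

    umi = rng.integers(0, 4 ** int(config.umi_length), total_mols, dtype=np.uint64)

    n_snps = len(snp_cat.categories)
    if config.mu_dup > 0:
        sd = config.dup_jackpot_sd
        if sd > 0:
            amp = rng.lognormal(-0.5 * sd * sd, sd, size=(n_snps, 2))
        else:
            amp = np.ones((n_snps, 2))
        allele_idx = (~is_ref).astype(np.int64)
        lam = config.mu_dup * amp[snp_codes[row_idx], allele_idx]
        copies = 1 + rng.poisson(lam)
    else:
        copies = np.ones(total_mols, dtype=np.int64)

    read_of_mol = np.repeat(np.arange(total_mols), copies)
    return pd.DataFrame(
        {
            "snp_id": pd.Categorical.from_codes(
                snp_codes[row_idx][read_of_mol], categories=snp_cat.categories
            ),
            "orientation": pd.Categorical.from_codes(
                orient_is_rev[row_idx][read_of_mol].astype(np.int8),
                categories=["forward", "reverse"],
            ),
            "allele": pd.Categorical.from_codes(
                (~is_ref)[read_of_mol].astype(np.int8), categories=["ref", "alt"]
            ),
            "umi": umi[read_of_mol],
            "replicate": rep[row_idx][read_of_mol].astype(np.int16),
            "fraction": pd.Categorical.from_codes(
                np.zeros(len(read_of_mol), dtype=np.int8), categories=["RNA"]
            ),
        }
    )


def simulate_binding_counts(
    designs: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bound/unbound allele counts and region-level totals.

    Returns ``(allele_counts, region_counts)``.  The unbound fraction keeps
    the library proportion; the bound fraction's reference proportion is
    ``expit(logit(p_dna) + gamma * scale_c)`` with a per-concentration
    scale factor (``conc_gamma_scales``).  Region-level bound totals are
    scaled by ``2**region_logfc_true``; footprint regions draw their log2
    occupancy effect around ``region_logfc_mean_fp``.
    """
    merged = _check_truth_covers(designs, truth)
    region_ids = designs.set_index("snp_id")["region_id"].reindex(merged["snp_id"]).to_numpy()
    rng = _rng(config, _STREAM_BINDING)
    n = len(merged)
    reps = int(config.n_bind_reps)
    p_dna = merged["p_dna_true"].to_numpy()
    gamma = merged["gamma_true"].to_numpy()
    lfc = merged["region_logfc_true"].to_numpy()

    allele_frames = []
    region_frames = []
    for ci in range(int(config.n_concentrations)):
        conc = CONCENTRATIONS[ci]
        scale = float(config.conc_gamma_scales[ci])
        p_by_fraction = {
            "unbound": p_dna,
            "bound": expit(logit(p_dna) + gamma * scale),
        }
        for fraction, p_mean in p_by_fraction.items():
            totals = _nb_draws(rng, config.fraction_depth_mean, config.nb_size, (n, reps))
            p_draw = _beta_mix(
                rng, np.broadcast_to(p_mean[:, None], (n, reps)), config.rho_true
            )
            ref = rng.binomial(totals, p_draw)
            allele_frames.append(
                pd.DataFrame(
                    {
                        "snp_id": np.repeat(merged["snp_id"].to_numpy(), reps),
                        "orientation": "pooled",
                        "replicate": np.tile(np.arange(1, reps + 1), n),
                        "fraction": fraction,
                        "concentration": conc,
                        "ref_count": ref.ravel(),
                        "alt_count": (totals - ref).ravel(),
                    }
                )
            )
            region_mean = config.fraction_depth_mean * (
                np.exp2(lfc) if fraction == "bound" else np.ones(n)
            )
            region_totals = _nb_region(rng, region_mean, config.nb_size, reps)
            region_frames.append(
                pd.DataFrame(
                    {
                        "region_id": np.repeat(region_ids, reps),
                        "sample_id": [
                            f"{fraction}_{conc}_r{j}"
                            for _ in range(n)
                            for j in range(1, reps + 1)
                        ],
                        "fraction": fraction,
                        "replicate": np.tile(np.arange(1, reps + 1), n),
                        "concentration": conc,
                        "count": region_totals.ravel(),
                    }
                )
            )
    return (
        pd.concat(allele_frames, ignore_index=True),
        pd.concat(region_frames, ignore_index=True),
    )


def _nb_region(
    rng: np.random.Generator, means: np.ndarray, size_param: float, reps: int
) -> np.ndarray:
    if math.isinf(size_param):
        return rng.poisson(np.broadcast_to(means[:, None], (len(means), reps)))
    p = size_param / (size_param + means)
    return rng.negative_binomial(
        size_param, np.broadcast_to(p[:, None], (len(means), reps))
    )


def simulate_all(config: SimConfig) -> dict:
    """Run every simulation stage; returns a dict of tables."""
    designs, truth = simulate_design(config)
    dna = simulate_dna_counts(designs, truth, config)
    molecules = simulate_rna_molecules(designs, truth, config)
    binding_counts, region_counts = simulate_binding_counts(designs, truth, config)
    return {
        "designs": designs,
        "truth": truth,
        "dna_counts": dna,
        "rna_molecules": molecules,
        "binding_counts": binding_counts,
        "region_counts": region_counts,
    }
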