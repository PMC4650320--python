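"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design end to end: five myeloid cell
types, four treatments (ctrl, IL10, LPS, IL10_LPS), two biological
replicates, negative-binomial counts (var = mu + alpha * mu^2) with
per-library size factors, and planted gene modules:

* an LPS-common module up-regulated by LPS in every cell type,
* disjoint LPS cell-type-specific modules,
* AIR genes — LPS-up genes additionally suppressed under IL10_LPS in the
  IL-10-responsive cell types (eosinophils are non-responsive by default,
  modelling their missing STAT3 phosphorylation),
* an IL-10-up module induced by IL10 in responsive cell types,
* cell-identity modules so that, as in real libraries, cell type rather
  than treatment dominates the variance.

Matched promoter sequences carry a controlled CpG dinucleotide rate (AIR
genes CpG-poor, the rest a rich/poor mixture) and, optionally, an exact
planted motif consensus; the PWM library pairs sharp planted matrices with
Dirichlet decoys.  Every output is a deterministic function of the config,
including its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import CELL_TYPES, TREATMENTS, CountMatrix, PWM, SampleMeta

BASES = np.array(list("ACGT"))

#: the 20 signalling-factor families used for family-level summaries
FAMILY_LABELS = (
    "interleukin", "chemokine", "tnf", "interferon", "growth_factor",
    "csf", "tgf_beta", "bmp", "wnt", "fgf",
    "egf", "pdgf", "vegf", "ephrin", "semaphorin",
    "complement", "defensin", "netrin", "angiopoietin", "other_cytokine",
)

PLANTED_CONSENSI = {
    "PLANTED_NFKB": "GGGACTTTCC",   # NF-kB-like decamer
    "PLANTED_IRF": "AAAGTGAAAGT",   # IRF/ISRE-like site
}


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Stage-keyed substream so toggling one stage never shifts another."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    cell_types: tuple[str, ...] = CELL_TYPES
    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 2
    baseline_mean: tuple[float, float] = (20.0, 2000.0)  # log-uniform range
    dispersion: float = 0.1
    lps_common_frac: float = 0.10
    lps_specific_frac: float = 0.10   # total across cell types, split evenly
    air_frac_of_lps: float = 0.30
    il10_up_frac: float = 0.05
    celltype_frac: float = 0.25       # cell-identity modules, split evenly
    lps_effect: float = 6.0
    air_suppression: float = 4.0
    il10_effect: float = 4.0
    celltype_effect: float = 6.0
    library_size_range: tuple[float, float] = (0.7, 1.4)
    library_size_factors: tuple[float, ...] | None = None
    air_shared: bool = False          # shared AIR module instead of per-cell-type
    nonresponsive_cell_types: tuple[str, ...] = ("eosinophil",)
    cg_rate_rich: float = 0.30        # P(next=G | current=C) in rich promoters
    cg_rate_poor: float = 0.02
    rich_prob_non_air: float = 0.5
    plant_motif_in: str = "air"       # air | not_air | none
    motif_id: str = "PLANTED_NFKB"
    n_decoy_pwms: int = 8
    cytokine_frac_of_lps: float = 0.25
    family_background_frac: float = 0.05
    promoter_flank: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.lps_common_frac + self.lps_specific_frac
            + self.il10_up_frac + self.celltype_frac
        )
        if fracs > 1.0 + 1e-12:
            raise ValueError(f"module fractions sum to {fracs:.3f} > 1")
        for name in ("lps_effect", "air_suppression", "il10_effect", "celltype_effect"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 (use 1 to disable)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.plant_motif_in not in ("air", "not_air", "none"):
            raise ValueError("plant_motif_in must be air, not_air or none")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @property
    def responsive(self) -> dict[str, bool]:
        return {ct: ct not in self.nonresponsive_cell_types for ct in self.cell_types}


@dataclass
class GroundTruth:
    """Planted labels: what the pipeline should recover."""

    lps_up: pd.DataFrame      # genes x cell types, bool
    air: pd.DataFrame         # genes x cell types, bool; air => lps_up
    il10_up: pd.DataFrame     # genes x cell types, bool
    cpg_class: pd.Series      # 'rich' | 'poor'
    planted_motif: pd.Series  # PWM id or '' when none
    family: pd.DataFrame      # long gene -> family table
    il10_responsive: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = (self.air & ~self.lps_up).to_numpy()
        if bad.any():
            raise ValueError("air=True requires lps_up=True in the same cell type")

    def air_sets(self) -> dict[str, set[str]]:
        return {
            ct: set(self.air.index[self.air[ct]])
            for ct in self.air.columns
            if self.il10_responsive.get(ct, True)
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table, one row per gene x cell type."""
        rows = []
        for ct in self.lps_up.columns:
            rows.append(pd.DataFrame({
                "gene": self.lps_up.index,
                "cell_type": ct,
                "lps_up": self.lps_up[ct].to_numpy(),
                "air": self.air[ct].to_numpy(),
                "il10_up": self.il10_up[ct].to_numpy(),
                "cpg_class": self.cpg_class.to_numpy(),
                "planted_motif": self.planted_motif.to_numpy(),
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# module layout and count simulation
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _assign_modules(config: SimulationConfig, rng: np.random.Generator):
    """Disjoint index blocks for the planted modules, over a permutation."""
    n = config.n_genes
    perm = rng.permutation(n)
    k_common = int(round(config.lps_common_frac * n))
    k_specific = int(round(config.lps_specific_frac * n / len(config.cell_types)))
    k_il10 = int(round(config.il10_up_frac * n))
    k_ident = int(round(config.celltype_frac * n / len(config.cell_types)))
    pos = 0

    def take(k):
        nonlocal pos
        block = perm[pos:pos + k]
        pos += k
        return block

    common = take(k_common)
    specific = {ct: take(k_specific) for ct in config.cell_types}
    il10 = take(k_il10)
    identity = {ct: take(k_ident) for ct in config.cell_types}
    return common, specific, il10, identity


def make_truth(config: SimulationConfig) -> GroundTruth:
    """Planted labels for a simulation config (deterministic in the seed)."""
    rng = rng_for(config.seed, "truth")
    n = config.n_genes
    genes = _gene_ids(n)
    cts = list(config.cell_types)
    common, specific, il10_block, _identity = _assign_modules(config, rng)

    lps_up = pd.DataFrame(False, index=genes, columns=cts)
    air = pd.DataFrame(False, index=genes, columns=cts)
    il10_up = pd.DataFrame(False, index=genes, columns=cts)
    responsive = config.responsive

    for ct in cts:
        idx = np.concatenate([common, specific[ct]])
        lps_up.iloc[idx, lps_up.columns.get_loc(ct)] = True
        if responsive[ct]:
            il10_up.iloc[il10_block, il10_up.columns.get_loc(ct)] = True

    if config.air_shared:
        k = int(round(config.air_frac_of_lps * len(common)))
        shared = rng.choice(common, size=k, replace=False)
        for ct in cts:
            if responsive[ct]:
                air.iloc[shared, air.columns.get_loc(ct)] = True
    else:
        for ct in cts:
            if not responsive[ct]:
                continue
            pool = np.concatenate([common, specific[ct]])
            k = int(round(config.air_frac_of_lps * len(pool)))
            chosen = rng.choice(pool, size=k, replace=False)
            air.iloc[chosen, air.columns.get_loc(ct)] = True

    air_anywhere = air.any(axis=1)
    cpg = np.where(
        air_anywhere,
        "poor",
        np.where(rng.random(n) < config.rich_prob_non_air, "rich", "poor"),
    )
    cpg_class = pd.Series(cpg, index=genes, name="cpg_class")

    planted = pd.Series("", index=genes, name="planted_motif")
    if config.plant_motif_in != "none":
        lps_anywhere = lps_up.any(axis=1)
        if config.plant_motif_in == "air":
            target = air_anywhere
        else:
            target = lps_anywhere & ~air_anywhere
        planted[target] = config.motif_id

    family = make_family_table(lps_up, config)
    return GroundTruth(
        lps_up=lps_up,
        air=air,
        il10_up=il10_up,
        cpg_class=cpg_class,
        planted_motif=planted,
        family=family,
        il10_responsive=responsive,
    )


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts for the full design, plus planted labels.

    The mean model multiplies a per-gene log-uniform baseline by the
    cell-identity effect, the LPS effect under {LPS, IL10_LPS} for LPS-up
    genes, the IL-10 effect under {IL10, IL10_LPS} for IL-10-up genes, and
    divides by the AIR suppression under IL10_LPS for AIR genes in
    responsive cell types.  Counts are NB(sf_s * mu, alpha); alpha = 0
    degenerates to Poisson.
    """
    truth = make_truth(config)
    rng = rng_for(config.seed, "counts")
    n = config.n_genes
    cts = list(config.cell_types)
    _common, _specific, _il10, identity = _assign_modules(
        config, rng_for(config.seed, "truth")
    )

    log_lo, log_hi = np.log(config.baseline_mean[0]), np.log(config.baseline_mean[1])
    baseline = np.exp(rng.uniform(log_lo, log_hi, size=n))

    samples: list[SampleMeta] = []
    for ct in cts:
        for tr in config.treatments:
            for rep in range(1, config.n_replicates + 1):
                samples.append(SampleMeta(f"{ct}_{tr}_r{rep}", ct, tr, rep))

    if config.library_size_factors is not None:
        sf = np.asarray(config.library_size_factors, dtype=float)
        if sf.size != len(samples):
            raise ValueError("library_size_factors length must match sample count")
    else:
        sf = rng.uniform(*config.library_size_range, size=len(samples))

    means = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        mu = baseline.copy()
        ident = identity[s.cell_type]
        mu[ident] *= config.celltype_effect
        if s.treatment in ("LPS", "IL10_LPS"):
            mu[truth.lps_up[s.cell_type].to_numpy()] *= config.lps_effect
        if s.treatment in ("IL10", "IL10_LPS"):
            mu[truth.il10_up[s.cell_type].to_numpy()] *= config.il10_effect
        if s.treatment == "IL10_LPS" and truth.il10_responsive[s.cell_type]:
            mu[truth.air[s.cell_type].to_numpy()] /= config.air_suppression
        means[:, j] = sf[j] * mu

    alpha = config.dispersion
    if alpha == 0:
        counts = rng.poisson(means)
    else:
        size = 1.0 / alpha
        counts = rng.negative_binomial(size, size / (size + means))
    df = pd.DataFrame(counts, index=_gene_ids(n),
                      columns=[s.sample_id for s in samples], dtype=np.int64)
    return CountMatrix(df, samples), truth


def simulate_two_group(
    n_genes: int = 5000,
    n_per_group: int = 3,
    mu: float = 100.0,
    alpha: float = 0.1,
    effect: float = 1.0,
    frac_de: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Minimal two-condition NB simulation for DE calibration and power.

    Returns a ctrl-vs-LPS macrophage matrix and the boolean planted-effect
    mask.  ``effect=1`` is the global null.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    n_de = int(round(frac_de * n_genes)) if effect != 1.0 else 0
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[rng.choice(n_genes, size=n_de, replace=False)] = True
    samples = [SampleMeta(f"macrophage_ctrl_r{i+1}", "macrophage", "ctrl", i + 1)
               for i in range(n_per_group)]
    samples += [SampleMeta(f"macrophage_LPS_r{i+1}", "macrophage", "LPS", i + 1)
                for i in range(n_per_group)]
    means = np.full((n_genes, 2 * n_per_group), float(mu))
    means[is_de, n_per_group:] *= effect
    if alpha == 0:
        counts = rng.poisson(means)
    else:
        size = 1.0 / alpha
        counts = rng.negative_binomial(size, size / (size + means))
    df = pd.DataFrame(counts, index=genes,
                      columns=[s.sample_id for s in samples], dtype=np.int64)
    return CountMatrix(df, samples), is_de


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _markov_windows(
    rng: np.random.Generator, cg_rates: np.ndarray, length: int
) -> np.ndarray:
    """Base-coded (n, length) sequences from a first-order chain where
    P(G | previous C) = cg_rates[i]; all other transitions are uniform."""
    n = cg_rates.size
    seq = np.empty((n, length), dtype=np.int8)
    cur = rng.integers(0, 4, size=n, dtype=np.int8)
    seq[:, 0] = cur
    other = np.array([0, 1, 3], dtype=np.int8)  # A, C, T after a C (non-CG)
    for pos in range(1, length):
        u = rng.random(n)
        fresh = rng.integers(0, 4, size=n, dtype=np.int8)
        alt = other[rng.integers(0, 3, size=n)]
        is_c = cur == 1
        nxt = np.where(is_c, np.where(u < cg_rates, np.int8(2), alt), fresh)
        cur = nxt.astype(np.int8)
        seq[:, pos] = cur
    return seq


def simulate_promoters(
    truth: GroundTruth,
    config: SimulationConfig,
    window_length: int = 500,
    tss_offset: int = 450,
) -> tuple[dict[str, str], list]:
    """Promoter contigs + TSS annotations matching the planted CpG classes.

    Each gene gets its own contig: the oriented promoter window (CpG-rich or
    CpG-poor Markov sequence, with the planted motif consensus overwritten
    at a uniform offset where assigned) embedded in random flanks, on a
    random strand.  Returns (contig sequences, GeneAnnotation list).
    """
    from .model import GeneAnnotation  # local import to avoid cycles

    flank = config.promoter_flank
    if window_length <= 0 or tss_offset >= window_length:
        raise ValueError("window must be positive with the TSS inside it")
    rng = rng_for(config.seed, "promoters")
    genes = list(truth.cpg_class.index)
    rates = np.where(
        truth.cpg_class.to_numpy() == "rich", config.cg_rate_rich, config.cg_rate_poor
    )
    windows = _markov_windows(rng, rates, window_length)

    consensus_codes = {
        pid: np.array(["ACGT".index(b) for b in cons], dtype=np.int8)
        for pid, cons in PLANTED_CONSENSI.items()
    }
    planted = truth.planted_motif.to_numpy()
    for i in np.flatnonzero(planted != ""):
        codes = consensus_codes[planted[i]]
        off = rng.integers(0, window_length - codes.size + 1)
        windows[i, off:off + codes.size] = codes

    strands = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    contig_len = window_length + 2 * flank
    seqs: dict[str, str] = {}
    annots = []
    comp = np.array([3, 2, 1, 0], dtype=np.int8)
    for i, gene in enumerate(genes):
        contig = rng.integers(0, 4, size=contig_len, dtype=np.int8)
        w = windows[i]
        if strands[i] == "+":
            # window = contig[tss-450, tss+50) => place at [flank, flank+L)
            contig[flank:flank + window_length] = w
            tss = flank + tss_offset
        else:
            # window = revcomp(contig[tss-(L-1-off), tss+off+1)) with
            # off = tss_offset; place revcomp(w) at [flank, flank+L)
            contig[flank:flank + window_length] = comp[w[::-1]]
            tss = flank + window_length - 1 - tss_offset
        name = f"chr_{gene}"
        seqs[name] = "".join(BASES[contig])
        annots.append(GeneAnnotation(gene=gene, sequence_id=name, tss=tss,
                                     strand=str(strands[i])))
    return seqs, annots


# ---------------------------------------------------------------------------
# PWM library and family table
# ---------------------------------------------------------------------------

def consensus_pwm(pwm_id: str, consensus: str, sharpness: float = 0.91) -> PWM:
    """Sharp PWM whose argmax per column is the consensus (IC > 1 bit/col)."""
    mat = np.full((len(consensus), 4), (1.0 - sharpness) / 3.0)
    for j, base in enumerate(consensus):
        mat[j, "ACGT".index(base)] = sharpness
    return PWM(id=pwm_id, name=pwm_id, matrix=mat)


def make_pwm_library(config: SimulationConfig) -> tuple[list[PWM], set[str]]:
    """Planted sharp PWMs plus Dirichlet-noise decoys.

    Returns (pwms, planted_ids); planted matrices come first and their
    consensus strings equal the sequences embedded by simulate_promoters.
    """
    rng = rng_for(config.seed, "pwms")
    pwms = [consensus_pwm(pid, cons) for pid, cons in PLANTED_CONSENSI.items()]
    planted_ids = {p.id for p in pwms}
    for k in range(config.n_decoy_pwms):
        width = int(rng.integers(8, 13))
        mat = rng.dirichlet(np.ones(4), size=width)
        pwms.append(PWM(id=f"DECOY_{k:02d}", name=f"DECOY_{k:02d}", matrix=mat))
    return pwms, planted_ids


def make_family_table(lps_up: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Gene -> family labels, concentrated among LPS-up genes.

    Mimics the observation that LPS-responsive genes are enriched for
    interleukins, chemokines and TNF-family members; a thin background of
    other families is scattered over the rest of the genome.
    """
    rng = rng_for(config.seed, "families")
    genes = np.asarray(lps_up.index)
    if genes.size == 0:
        return pd.DataFrame(columns=["gene", "family"])
    lps_anywhere = lps_up.any(axis=1).to_numpy()
    rows: list[tuple[str, str]] = []
    core = ("interleukin", "chemokine", "tnf")
    for g in genes[lps_anywhere]:
        if rng.random() < config.cytokine_frac_of_lps:
            if rng.random() < 0.8:
                fam = core[rng.integers(0, len(core))]
            else:
                fam = FAMILY_LABELS[rng.integers(0, len(FAMILY_LABELS))]
            rows.append((g, fam))
    for g in genes[~lps_anywhere]:
        if rng.random() < config.family_background_frac:
            rows.append((g, FAMILY_LABELS[rng.integers(0, len(FAMILY_LABELS))]))
    return pd.DataFrame(rows, columns=["gene", "family"])
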