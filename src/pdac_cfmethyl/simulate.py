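"""Synthetic cohort generator.

Emulates the statistical structure the diagnostic analysis assumes: a CpG
landscape with planted differentially methylated regions (DMRs), paired
tumor/NAT bisulfite count tables with beta-binomial overdispersion, plasma
samples as tumor-fraction mixtures (including the observed tissue-plasma
discordance of hypomethylated DMRs, which tend to show *elevated* methylation
in cancer plasma), clonal-hematopoiesis (CH) contaminated variant tables with
matched WBC counterparts, and class-conditional lognormal CA19-9 values.

All randomness flows through numpy Generators derived from ``SimConfig.seed``;
identical configs produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CpGCountTable, validate_sample_sheet

# stream labels mixed into the seed so each generative stage has an
# independent, reproducible stream
_S_LANDSCAPE, _S_PLANT, _S_TISSUE, _S_PLASMA, _S_VARIANTS, _S_CA199 = range(1, 7)

STAGES = ("0", "I", "II", "III", "IV")

# stage -> band used for the monotone stage/tumor-fraction map (0 shares the
# lowest band with I; both are reported together downstream)
STAGE_BAND = {"0": 0, "I": 0, "II": 1, "III": 2, "IV": 3}
N_BANDS = 4

DEFAULT_HOTSPOTS: tuple[tuple[str, str], ...] = (
    ("KRAS", "G12"), ("KRAS", "Q61"), ("TP53", "R249"), ("TP53", "R175"),
    ("TP53", "R273"), ("CDKN2A", "R58"), ("SMAD4", "R361"), ("GNAS", "R201"),
    ("BRAF", "V600"), ("PIK3CA", "E545"),
)

# per-patient probability that a PDAC tumor carries a (clonal) driver
# mutation in each gene; roughly mirrors the cfDNA detection spectrum
# (KRAS and TP53 dominant, long tail of other drivers)
DEFAULT_TUMOR_GENE_PROBS: tuple[tuple[str, float], ...] = (
    ("KRAS", 0.55), ("TP53", 0.40), ("GNAS", 0.10), ("CDKN2A", 0.09),
    ("SMAD4", 0.09), ("ARID1A", 0.06), ("RNF43", 0.05), ("PIK3CA", 0.04),
    ("BRAF", 0.03), ("ATM", 0.03),
)

# genes in which clonal-hematopoiesis variants are planted
CH_GENES = ("TP53", "GNAS", "ATM", "ARID1A", "CHEK2")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Ca199Params:
    """Class-conditional lognormal CA19-9 model (U/mL).

    Defaults reproduce median (IQR) 149.1 (39.75-598) for PDAC and
    7.8 (5.08-11.39) for healthy controls: mu = ln(median), sigma =
    ln(q3/q1) / (2 * 0.6745).
    """

    pdac_mu: float = math.log(149.1)
    pdac_sigma: float = math.log(598.0 / 39.75) / (2 * 0.6745)
    healthy_mu: float = math.log(7.8)
    healthy_sigma: float = math.log(11.39 / 5.08) / (2 * 0.6745)
    # if set, the fraction of PDAC draws forced below the 37.0 U/mL clinical
    # cutoff (CA19-9-negative subgroup); None leaves the natural fraction
    # (~0.24 at the defaults)
    pdac_negative_fraction: float | None = None


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    # landscape
    n_cpg: int = 100_000
    n_chrom: int = 5
    mean_spacing_bp: int = 30
    # cohort sizes
    n_tissue_pairs: int = 32
    n_pdac_plasma: int = 255
    n_healthy_plasma: int = 209
    # planted DMRs
    n_hyper: int = 50
    n_hypo: int = 60
    effect_size: float = 0.3
    dmr_len_bp: tuple[int, int] = (200, 500)
    min_dmr_separation_bp: int = 2000
    # sequencing / noise model
    coverage_mean: float = 30.0
    bb_dispersion: float = 0.1
    plasma_coverage_mean: float = 150.0
    plasma_dispersion: float = 0.003
    # plasma mixture
    tumor_fraction_range: tuple[float, float] = (0.01, 0.2)
    hypo_discordance_prob: float = 0.7
    stage_probs: tuple[tuple[str, float], ...] = (
        ("0", 0.01), ("I", 0.32), ("II", 0.23), ("III", 0.14), ("IV", 0.30))
    # variants
    ch_rate: float = 0.2
    ch_af_range: tuple[float, float] = (0.001, 0.01)
    ch_af_noise_sigma: float = 0.1
    background_variant_rate: float = 0.25
    af_detection_limit: float = 0.0003
    hotspot_defs: tuple[tuple[str, str], ...] = DEFAULT_HOTSPOTS
    tumor_gene_probs: tuple[tuple[str, float], ...] = DEFAULT_TUMOR_GENE_PROBS
    # CA19-9
    ca199_params: Ca199Params = field(default_factory=Ca199Params)

    def __post_init__(self) -> None:
        if self.n_cpg < 0 or self.n_chrom <= 0:
            raise ConfigError("n_cpg must be >= 0 and n_chrom positive")
        if self.mean_spacing_bp < 1:
            raise ConfigError("mean_spacing_bp must be >= 1")
        if self.n_tissue_pairs < 0 or self.n_pdac_plasma < 0 or self.n_healthy_plasma < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if not (0 < self.effect_size <= 1):
            raise ConfigError("effect_size must be in (0, 1]")
        if self.dmr_len_bp[0] < 50 or self.dmr_len_bp[0] > self.dmr_len_bp[1]:
            raise ConfigError("dmr_len_bp must be an increasing range with lower bound >= 50")
        if not (0 <= self.bb_dispersion < 1) or not (0 <= self.plasma_dispersion < 1):
            raise ConfigError("dispersions must be in [0, 1)")
        lo, hi = self.tumor_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("tumor_fraction_range must be within [0, 1]")
        for p in (self.hypo_discordance_prob, self.ch_rate, self.background_variant_rate):
            if not (0 <= p <= 1):
                raise ConfigError("probabilities must be in [0, 1]")
        if self.coverage_mean <= 0 or self.plasma_coverage_mean <= 0:
            raise ConfigError("coverage means must be positive")
        total = sum(p for _, p in self.stage_probs)
        if abs(total - 1.0) > 1e-6:
            raise ConfigError("stage_probs must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass(frozen=True)
class TrueDMR:
    """Ground-truth planted region (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    direction: str  # hyper | hypo
    effect_size: float
    plasma_concordant: bool
    n_cpg: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 50:
            raise ConfigError("TrueDMR shorter than 50 bp")
        if self.n_cpg < 3:
            raise ConfigError("TrueDMR with fewer than 3 CpGs")


@dataclass
class MethylationProfile:
    """Per-CpG mean methylation profiles underlying the simulation.

    ``baseline`` is shared by NAT tissue and healthy plasma background;
    ``tumor`` shifts the baseline by +/- effect inside planted DMRs;
    ``plasma_tumor`` is the tumor profile *as seen from plasma*: for
    discordant hypo-DMRs the tumor-derived plasma signal is elevated
    rather than depressed.
    """

    baseline: dict[str, np.ndarray]
    tumor: dict[str, np.ndarray]
    plasma_tumor: dict[str, np.ndarray]


Landscape = dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# landscape and DMR planting
# ---------------------------------------------------------------------------

def generate_cpg_landscape(config: SimConfig) -> Landscape:
    """Ordered CpG positions per chromosome, geometric inter-CpG spacing."""
    rng = config.rng(_S_LANDSCAPE)
    landscape: Landscape = {}
    counts = [config.n_cpg // config.n_chrom] * config.n_chrom
    for i in range(config.n_cpg % config.n_chrom):
        counts[i] += 1
    for c, n in enumerate(counts, start=1):
        name = f"chr{c}"
        if n == 0:
            landscape[name] = np.array([], dtype=np.int64)
            continue
        spacing = rng.geometric(1.0 / config.mean_spacing_bp, size=n)
        # geometric draws are >= 1, so positions are strictly increasing
        landscape[name] = 1000 + np.cumsum(spacing.astype(np.int64))
    return landscape


def _draw_baseline(landscape: Landscape, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Bimodal block-wise baseline: CGI-like low blocks, open-sea-like high."""
    baseline = {}
    for chrom, pos in landscape.items():
        n = len(pos)
        level = np.empty(n)
        i = 0
        while i < n:
            block = int(rng.geometric(1.0 / 15))
            if rng.random() < 0.35:
                mu = rng.uniform(0.05, 0.25)
            else:
                mu = rng.uniform(0.70, 0.95)
            j = min(n, i + block)
            level[i:j] = np.clip(mu + rng.normal(0, 0.02, j - i), 0.02, 0.98)
            i = j
        baseline[chrom] = level
    return baseline


def plant_dmrs(landscape: Landscape, config: SimConfig
               ) -> tuple[list[TrueDMR], MethylationProfile]:
    """Plant non-overlapping hyper/hypo DMRs and build the mean profiles.

    Raises :class:`ConfigError` if the landscape cannot host the requested
    number of regions at the required separation (no silent truncation).
    """
    rng = config.rng(_S_PLANT)
    baseline = _draw_baseline(landscape, rng)
    tumor = {c: b.copy() for c, b in baseline.items()}
    plasma_tumor = {c: b.copy() for c, b in baseline.items()}

    n_wanted = config.n_hyper + config.n_hypo
    directions = ["hyper"] * config.n_hyper + ["hypo"] * config.n_hypo
    rng.shuffle(directions)

    chroms = [c for c in landscape if len(landscape[c]) >= 3]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    dmrs: list[TrueDMR] = []
    max_tries = max(200, 60 * n_wanted)
    tries = 0
    for direction in directions:
        ok = False
        while tries < max_tries and not ok:
            tries += 1
            chrom = chroms[int(rng.integers(len(chroms)))] if chroms else None
            if chrom is None:
                break
            pos = landscape[chrom]
            i0 = int(rng.integers(len(pos)))
            length = int(rng.integers(config.dmr_len_bp[0], config.dmr_len_bp[1] + 1))
            start = int(pos[i0])
            end = start + length - 1
            sel = (pos >= start) & (pos <= end)
            idx = np.flatnonzero(sel)
            if len(idx) < 3:
                continue
            end = int(pos[idx[-1]])
            if end - start + 1 < max(50, config.dmr_len_bp[0]):
                continue
            sep = config.min_dmr_separation_bp
            if any(start - sep <= e and end + sep >= s for s, e in placed[chrom]):
                continue
            # region-level baseline compatible with the planted shift
            if direction == "hyper":
                base_mu = rng.uniform(0.10, 0.40)
                shift = config.effect_size
            else:
                base_mu = rng.uniform(0.60, 0.90)
                shift = -config.effect_size
            jitter = rng.normal(0, 0.02, len(idx))
            if shift > 0:
                b = np.clip(base_mu + jitter, 0.02, 0.98 - shift)
            else:
                b = np.clip(base_mu + jitter, 0.02 - shift, 0.98)
            baseline[chrom][idx] = b
            tumor[chrom][idx] = b + shift
            concordant = True
            if direction == "hypo":
                concordant = bool(rng.random() >= config.hypo_discordance_prob)
            # discordant hypo-DMRs contribute an *elevated* plasma signal
            plasma_shift = shift if concordant else abs(shift)
            plasma_tumor[chrom][idx] = np.clip(b + plasma_shift, 0.01, 0.99)
            placed[chrom].append((start, end))
            dmrs.append(TrueDMR(chrom, start, end, direction,
                                config.effect_size, concordant, len(idx)))
            ok = True
        if not ok:
            raise ConfigError(
                f"landscape too small to place {n_wanted} DMRs "
                f"(placed {len(dmrs)} after {tries} tries)")
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs, MethylationProfile(baseline, tumor, plasma_tumor)


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def _beta_binomial(rng: np.random.Generator, n: np.ndarray, mu: np.ndarray,
                   phi: float) -> np.ndarray:
    """Beta-binomial draws with mean n*mu and intra-class correlation phi.

    Variance is n*mu*(1-mu)*(1 + (n-1)*phi); phi == 0 degenerates to
    plain binomial sampling.
    """
    if phi <= 0:
        return rng.binomial(n, mu)
    s = 1.0 / phi - 1.0  # a + b of the mixing beta
    a = np.clip(mu * s, 1e-8, None)
    b = np.clip((1.0 - mu) * s, 1e-8, None)
    p = rng.beta(a, b)
    return rng.binomial(n, p)


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, coverage_mean: float,
                   phi: float) -> tuple[np.ndarray, np.ndarray]:
    n = rng.poisson(coverage_mean, size=len(mu))
    m = _beta_binomial(rng, n, mu, phi)
    return m, n


def _profile_table(rng: np.random.Generator, sample_id: str, landscape: Landscape,
                   profile: dict[str, np.ndarray], coverage_mean: float,
                   phi: float) -> CpGCountTable:
    chroms, poss, ms, ns = [], [], [], []
    for chrom in sorted(landscape):
        pos = landscape[chrom]
        if len(pos) == 0:
            continue
        m, n = _sample_counts(rng, profile[chrom], coverage_mean, phi)
        chroms.append(np.repeat(chrom, len(pos)))
        poss.append(pos)
        ms.append(m)
        ns.append(n)
    if not chroms:
        return CpGCountTable(sample_id, pd.DataFrame(
            columns=["chrom", "pos", "n_meth", "n_total"]))
    return CpGCountTable.from_arrays(
        sample_id, np.concatenate(chroms), np.concatenate(poss),
        np.concatenate(ms), np.concatenate(ns))


def simulate_tissue_pairs(landscape: Landscape, profile: MethylationProfile,
                          config: SimConfig
                          ) -> tuple[list[CpGCountTable], list[CpGCountTable]]:
    """Paired tumor / NAT count tables (T001/N001, ...)."""
    if config.n_tissue_pairs < 2:
        raise ConfigError("need at least 2 tissue pairs")
    rng = config.rng(_S_TISSUE)
    tumor_tables, nat_tables = [], []
    for k in range(config.n_tissue_pairs):
        tumor_tables.append(_profile_table(
            rng, f"T{k + 1:03d}", landscape, profile.tumor,
            config.coverage_mean, config.bb_dispersion))
        nat_tables.append(_profile_table(
            rng, f"N{k + 1:03d}", landscape, profile.baseline,
            config.coverage_mean, config.bb_dispersion))
    return tumor_tables, nat_tables


# ---------------------------------------------------------------------------
# plasma cohort
# ---------------------------------------------------------------------------

def _draw_tumor_fraction(rng: np.random.Generator, stage: str,
                         config: SimConfig) -> float:
    """Monotone stage -> tumor fraction map.

    Stage band b confines f to the b-th quarter of the log-scale range, so
    higher stages have stochastically larger fractions (stage 0 shares the
    lowest band with stage I).
    """
    lo, hi = config.tumor_fraction_range
    if hi <= 0:
        return 0.0
    lo = max(lo, 1e-6)
    band = STAGE_BAND[stage]
    u = rng.random()
    return float(lo * (hi / lo) ** ((band + u) / N_BANDS))


def simulate_plasma_cohort(landscape: Landscape, profile: MethylationProfile,
                           config: SimConfig
                           ) -> tuple[list[CpGCountTable], pd.DataFrame]:
    """Plasma count tables plus the sample sheet.

    PDAC plasma per-CpG mean = (1-f) * baseline + f * plasma-tumor profile,
    with f drawn from the stage-linked map; healthy plasma is pure baseline.
    """
    rng = config.rng(_S_PLASMA)
    stages, probs = zip(*config.stage_probs)
    rows = []
    tables: list[CpGCountTable] = []
    for i in range(config.n_pdac_plasma):
        sid = f"P{i + 1:03d}"
        stage = str(rng.choice(stages, p=probs))
        f = _draw_tumor_fraction(rng, stage, config)
        mix = {c: (1 - f) * profile.baseline[c] + f * profile.plasma_tumor[c]
               for c in landscape}
        tables.append(_profile_table(rng, sid, landscape, mix,
                                     config.plasma_coverage_mean,
                                     config.plasma_dispersion))
        cohort = "cohort1" if rng.random() < 0.65 else "cohort2"
        rows.append((sid, "PDAC", cohort, stage, f))
    for i in range(config.n_healthy_plasma):
        sid = f"H{i + 1:03d}"
        tables.append(_profile_table(rng, sid, landscape, profile.baseline,
                                     config.plasma_coverage_mean,
                                     config.plasma_dispersion))
        cohort = "cohort3" if rng.random() < 0.4 else "cohort4"
        rows.append((sid, "healthy", cohort, "NA", 0.0))
    sheet = pd.DataFrame(rows, columns=["sample_id", "group", "cohort",
                                        "stage", "tumor_fraction"])
    sheet["ca19_9"] = np.nan
    sheet["split"] = "NA"
    return tables, validate_sample_sheet(sheet)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _variant_record(rng: np.random.Generator, sample_id: str, gene: str,
                    residue: str | None, af: float) -> dict:
    """One synthetic variant row; coordinates are arbitrary but reproducible."""
    if residue is None:
        residue = f"{_AA[int(rng.integers(20))]}{int(rng.integers(30, 900))}"
    alt_aa = _AA[int(rng.integers(20))]
    chrom = f"chr{int(rng.integers(1, 23))}"
    pos = int(rng.integers(1_000_000, 50_000_000))
    bases = "ACGT"
    ref = bases[int(rng.integers(4))]
    alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
    return {
        "sample_id": sample_id, "gene": gene, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": alt, "allele_fraction": float(af),
        "protein_change": f"{residue}{alt_aa}", "non_synonymous": True,
        "wbc_shared": False,
    }


def simulate_variants(config: SimConfig, sample_sheet: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """cfDNA and matched-WBC variant tables.

    CH variants appear in both compartments of the same individual with
    multiplicative lognormal AF noise; tumor variants appear only in PDAC
    cfDNA with AF proportional to that sample's tumor fraction; a low-rate
    background of non-CH somatic variants affects everyone.
    """
    rng = config.rng(_S_VARIANTS)
    hotspot_by_gene: dict[str, list[str]] = {}
    for gene, res in config.hotspot_defs:
        hotspot_by_gene.setdefault(gene, []).append(res)
    cf_rows: list[dict] = []
    wbc_rows: list[dict] = []
    for _, s in sample_sheet.iterrows():
        sid = s["sample_id"]
        f = float(s.get("tumor_fraction", 0.0) or 0.0)
        if s["group"] == "PDAC" and f > 0:
            for gene, p_gene in config.tumor_gene_probs:
                if rng.random() >= p_gene:
                    continue
                residue = None
                if gene in hotspot_by_gene and rng.random() < 0.8:
                    residue = hotspot_by_gene[gene][
                        int(rng.integers(len(hotspot_by_gene[gene])))]
                af = f * rng.uniform(0.1, 0.6)
                if af < config.af_detection_limit:
                    continue
                cf_rows.append(_variant_record(rng, sid, gene, residue, min(af, 1.0)))
        if rng.random() < config.ch_rate:
            n_ch = 1 + int(rng.poisson(0.5))
            for _ in range(n_ch):
                gene = CH_GENES[int(rng.integers(len(CH_GENES)))]
                lo, hi = config.ch_af_range
                af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                rec = _variant_record(rng, sid, gene, None, af)
                cf_rows.append(rec)
                wbc_af = af * float(np.exp(rng.normal(0.0, config.ch_af_noise_sigma)))
                wbc = dict(rec)
                wbc["allele_fraction"] = float(np.clip(wbc_af, 1e-6, 1.0))
                wbc_rows.append(wbc)
        if rng.random() < config.background_variant_rate:
            gene = CH_GENES[int(rng.integers(len(CH_GENES)))]
            af = float(np.exp(rng.uniform(np.log(5e-4), np.log(8e-3))))
            cf_rows.append(_variant_record(rng, sid, gene, None, af))
    cols = ["sample_id", "gene", "chrom", "pos", "ref", "alt",
            "allele_fraction", "protein_change", "non_synonymous", "wbc_shared"]
    cfdna = pd.DataFrame(cf_rows, columns=cols)
    wbc = pd.DataFrame(wbc_rows, columns=cols)
    return cfdna, wbc


# ---------------------------------------------------------------------------
# CA19-9
# ---------------------------------------------------------------------------

CA199_CUTOFF = 37.0


def simulate_ca199(sample_sheet: pd.DataFrame, config: SimConfig) -> pd.Series:
    """Lognormal CA19-9 values (U/mL) indexed by sample id."""
    rng = config.rng(_S_CA199)
    p = config.ca199_params
    values = {}
    for _, s in sample_sheet.iterrows():
        if s["group"] == "PDAC":
            mu, sigma = p.pdac_mu, p.pdac_sigma
            if p.pdac_negative_fraction is not None:
                want_negative = rng.random() < p.pdac_negative_fraction
                v = _lognormal_truncated(rng, mu, sigma, CA199_CUTOFF, want_negative)
            else:
                v = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else math.exp(mu)
        else:
            mu, sigma = p.healthy_mu, p.healthy_sigma
            v = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else math.exp(mu)
        values[s["sample_id"]] = v
    return pd.Series(values, name="ca19_9")


def _lognormal_truncated(rng: np.random.Generator, mu: float, sigma: float,
                         cutoff: float, below: bool) -> float:
    if sigma <= 0:
        return math.exp(mu)
    for _ in range(10_000):
        v = float(np.exp(rng.normal(mu, sigma)))
        if (v < cutoff) == below:
            return v
    return cutoff * (0.99 if below else 1.01)  # pathological params fallback


# ---------------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Everything one simulated study produces."""

    config: SimConfig
    landscape: Landscape
    true_dmrs: list[TrueDMR]
    profile: MethylationProfile
    tumor_tables: list[CpGCountTable]
    nat_tables: list[CpGCountTable]
    plasma_tables: list[CpGCountTable]
    sample_sheet: pd.DataFrame
    cfdna_variants: pd.DataFrame
    wbc_variants: pd.DataFrame


def simulate_cohort(config: SimConfig) -> Cohort:
    """Run every generative stage under one config."""
    landscape = generate_cpg_landscape(config)
    true_dmrs, profile = plant_dmrs(landscape, config)
    tumor_tables, nat_tables = simulate_tissue_pairs(landscape, profile, config)
    plasma_tables, sheet = simulate_plasma_cohort(landscape, profile, config)
    cfdna, wbc = simulate_variants(config, sheet)
    ca199 = simulate_ca199(sheet, config)
    sheet = sheet.copy()
    sheet["ca19_9"] = sheet["sample_id"].map(ca199)
    return Cohort(config, landscape, true_dmrs, profile, tumor_tables,
                  nat_tables, plasma_tables, sheet, cfdna, wbc)


def true_dmrs_to_frame(dmrs: Sequence[TrueDMR]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": d.chrom, "start": d.start, "end": d.end,
        "direction": d.direction, "mean_diff":
            d.effect_size if d.direction == "hyper" else -d.effect_size,
        "plasma_concordant": d.plasma_concordant, "n_cpg": d.n_cpg,
    } for d in dmrs])
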