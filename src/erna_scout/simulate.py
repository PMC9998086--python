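"""Synthetic two-cohort eRNA study with machine-readable ground truth.

Emulates the statistical structure of a Barrett's-oesophagus ("BO", cohort
A) versus oesophageal-adenocarcinoma ("OAC", cohort B) eRNA discovery
study on a toy genome:

* a multi-chromosome genome with well-separated genes;
* open-chromatin peaks that are either truly intergenic or "decoys" placed
  inside gene exclusion zones (gene body +2 kb upstream/+500 bp
  downstream), to exercise the truncated-genome filter;
* stranded RNA fragments per sample whose region counts are negative
  binomial (Var = mu + alpha*mu^2) with lognormal per-sample depth; a
  planted subset of intergenic peaks is differentially transcribed between
  cohorts at a known log2 fold change, in a known direction (gained or
  lost from A to B); fragments split between strands by the bidirectional
  fraction, so directionality scores concentrate near 1;
* a gene-expression matrix (log2 scale) in which each planted eRNA's
  designated target gene is coupled to the eRNA's standardised signal with
  strength gamma, and every gene additionally shifts between cohorts in
  proportion to its true net eRNA change within 200 kb of its TSS;
* survival times with hazard exp(sum beta_i x_i) over standardised
  expression of chosen genes, with uniform independent censoring.

A quiet fraction of background peaks transcribes at sub-threshold levels so
the count/FPM candidate filter has work to do.  All randomness flows from
one master seed through per-stage child streams (genome, counts, survival),
so partial re-runs are reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import (
    GenomeAnnotation,
    Gene,
    Interval,
    RegionSet,
    TruncationParams,
    build_exclusion_zones,
)
from .quantify import FragmentSet
from .survival import SurvivalData

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "SimulatedCounts",
    "simulate_genome",
    "simulate_counts",
    "simulate_survival",
    "simulate_survival_cohort",
    "simulate_dataset",
    "write_dataset",
    "match_planted_regions",
]

COHORT_A = "BO"
COHORT_B = "OAC"


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort experiment.

    Defaults: 2 chromosomes x 2 Mb carrying 60 genes, 300 intergenic peaks
    (40 of them planted differential eRNAs at |log2FC| = 2) plus 100 decoy
    peaks inside exclusion zones, and 20 + 20 samples of NB counts with
    mean 50 and dispersion 0.1.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 60
    n_intergenic_peaks: int = 300
    n_decoy_peaks: int = 100
    n_planted_ernas: int = 40
    n_a: int = 20
    n_b: int = 20
    nb_mean: float = 50.0
    nb_dispersion: float = 0.1
    planted_dispersion: float = 0.7    # differential eRNAs: strong biological
                                       # heterogeneity across patients
    quiet_fraction: float = 0.25       # background peaks transcribed below threshold
    quiet_mean: float = 0.5
    planted_log2fc: float = 2.0
    bidirectional_fraction: float = 0.5
    fragment_length: int = 100
    depth_sd: float = 0.2              # lognormal sigma of per-sample depth
    coupling_gamma: float = 2.0        # eRNA -> target coupling weight
    expression_noise_sd: float = 1.0   # residual noise of enhancer-driven
                                       # targets; gamma/noise_sd = signal:noise
    background_gene_sd: float = 2.5    # idiosyncratic variation of genes not
                                       # coupled to a measured enhancer
    erna_offset_min: int = 5_000
    erna_offset_max: int = 30_000
    peak_width_min: int = 300
    peak_width_max: int = 800
    peak_jitter: int = 40
    min_peak_separation: int = 2_500
    survival_beta: dict[str, float] = field(default_factory=dict)
    default_survival_beta: float = 0.7
    censoring_fraction: float = 0.2
    baseline_hazard: float = 0.02      # events per month
    net_window: int = 200_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_planted_ernas > self.n_intergenic_peaks:
            raise ValueError("planted eRNAs must be a subset of intergenic peaks")
        if not (0 <= self.bidirectional_fraction <= 1):
            raise ValueError("bidirectional_fraction must lie in [0, 1]")
        if not (0 <= self.quiet_fraction <= 1) or not (0 <= self.censoring_fraction < 1):
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_a, self.n_b) < 2:
            raise ValueError("cohort sizes must be >= 2")

    def rngs(self) -> dict[str, np.random.Generator]:
        """One child stream per artefact, derived from the master seed."""
        genome_ss, counts_ss, surv_ss = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "genome": np.random.default_rng(genome_ss),
            "counts": np.random.default_rng(counts_ss),
            "survival": np.random.default_rng(surv_ss),
        }


@dataclass
class SimulatedGenome:
    annotation: GenomeAnnotation
    peaks: RegionSet                    # all true peaks (intergenic + decoys), sorted
    truth: dict                         # planted structure (see simulate_genome)


@dataclass
class SimulatedCounts:
    fragment_sets: list[FragmentSet]
    gene_expression: pd.DataFrame       # genes x samples, log2 scale
    metadata: pd.DataFrame              # sample_id, cohort
    truth: dict


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[Gene]:
    genes: list[Gene] = []
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    gid = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        n = per_chrom[c]
        if n == 0:
            continue
        slot = cfg.chrom_length // (n + 1)
        if slot < 20_000:
            raise ValueError(
                "infeasible packing: genes too dense; increase chrom_length"
            )
        for k in range(n):
            length = int(rng.integers(2_000, 8_001))
            jitter = int(rng.integers(-slot // 8, slot // 8 + 1))
            start = (k + 1) * slot + jitter
            start = int(np.clip(start, 3_000, cfg.chrom_length - length - 3_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(Gene(f"G{gid:03d}", chrom, start, start + length, strand))
    return genes


def _interval_clear(
    iv: tuple[str, int, int],
    exclusion: dict[str, list[tuple[int, int]]],
    placed: dict[str, list[int]],
    min_sep: int,
) -> bool:
    chrom, s, e = iv
    for zs, ze in exclusion.get(chrom, ()):
        if s < ze and zs < e:
            return False
    c = (s + e) // 2
    return all(abs(c - pc) >= min_sep for pc in placed.get(chrom, ()))


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulatedGenome:
    """Toy genome: genes, intergenic peaks (some planted), decoy peaks."""
    rng = rng or cfg.rngs()["genome"]
    genes = _place_genes(cfg, rng)
    chrom_sizes = {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)}
    ann = GenomeAnnotation(genes, chrom_sizes)
    zones = build_exclusion_zones(ann, TruncationParams())
    excl = {
        chrom: [(iv.start, iv.end) for iv in ivs]
        for chrom, ivs in zones.by_chrom().items()
    }
    placed: dict[str, list[int]] = {}

    def register(chrom: str, s: int, e: int) -> None:
        placed.setdefault(chrom, []).append((s + e) // 2)

    # --- planted eRNAs near designated target genes -----------------------
    # Target genes occupy every other gene along each chromosome so that
    # no two targets share a correlation window; directions are assigned
    # in contiguous genomic runs (coherent gained or lost enhancer
    # domains), so a target's net eRNA change never opposes its own eRNA
    # and domain boundaries populate the small net-change bins.  Periodic
    # targets host two eRNAs, populating the outer bins.
    n_double_genes = (cfg.n_planted_ernas // 4) if cfg.n_planted_ernas >= 8 else 0
    n_targets = cfg.n_planted_ernas - n_double_genes
    ordered = sorted(range(len(genes)), key=lambda i: (genes[i].chrom, genes[i].tss))
    spaced: list[int] = []
    by_chrom_idx: dict[str, list[int]] = {}
    for i in ordered:
        by_chrom_idx.setdefault(genes[i].chrom, []).append(i)
    for chrom in sorted(by_chrom_idx):
        parity = int(rng.integers(2))
        spaced.extend(by_chrom_idx[chrom][parity::2])
    if n_targets > len(spaced):
        raise ValueError(
            "infeasible packing: not enough spaced target genes; "
            "increase n_genes or reduce n_planted_ernas"
        )
    keep = rng.choice(len(spaced), size=n_targets, replace=False)
    target_idx = sorted(
        (spaced[k] for k in keep), key=lambda i: (genes[i].chrom, genes[i].tss)
    )
    directions = [1 if (rank // 4) % 2 == 0 else -1 for rank in range(n_targets)]
    multiplicities = []
    quota = n_double_genes
    for rank in range(n_targets):
        if rank % 3 == 0 and quota > 0:
            multiplicities.append(2)
            quota -= 1
        else:
            multiplicities.append(1)
    if quota > 0:  # leftover doubles: fill from the front among singles
        for rank in range(n_targets):
            if quota == 0:
                break
            if multiplicities[rank] == 1:
                multiplicities[rank] = 2
                quota -= 1

    planted: list[dict] = []
    erna_id = 0
    for gi, mult, direction in zip(target_idx, multiplicities, directions):
        g = genes[gi]
        upstream_sign = -1 if g.strand == "+" else 1  # away from the gene body
        for _ in range(mult):
            ok = False
            for _try in range(400):
                width = int(rng.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
                offset = int(rng.integers(cfg.erna_offset_min, cfg.erna_offset_max + 1))
                centre = g.tss + upstream_sign * offset
                s, e = centre - width // 2, centre - width // 2 + width
                if s < 0 or e > cfg.chrom_length:
                    continue
                if _interval_clear((g.chrom, s, e), excl, placed, cfg.min_peak_separation):
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    "infeasible packing: could not place a planted eRNA; "
                    "increase chrom_length or widen offsets"
                )
            erna_id += 1
            register(g.chrom, s, e)
            planted.append(
                {
                    "name": f"erna_{erna_id:03d}",
                    "chrom": g.chrom,
                    "start": int(s),
                    "end": int(e),
                    "direction": int(direction),
                    "target_gene": g.gene_id,
                }
            )

    # --- background intergenic peaks --------------------------------------
    n_bg = cfg.n_intergenic_peaks - cfg.n_planted_ernas
    n_quiet = int(round(cfg.quiet_fraction * n_bg))
    background: list[dict] = []
    chroms = sorted(chrom_sizes)
    for i in range(n_bg):
        ok = False
        for _try in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            width = int(rng.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
            s = int(rng.integers(1_000, cfg.chrom_length - width - 1_000))
            e = s + width
            if _interval_clear((chrom, s, e), excl, placed, cfg.min_peak_separation):
                ok = True
                break
        if not ok:
            raise ValueError(
                "infeasible packing: background peaks do not fit; increase chrom_length"
            )
        register(chrom, s, e)
        background.append(
            {
                "name": f"peak_{i + 1:03d}",
                "chrom": chrom,
                "start": s,
                "end": e,
                "quiet": i < n_quiet,
            }
        )

    # --- decoy peaks inside exclusion zones --------------------------------
    # decoys need wide separation only from real peaks; decoy-decoy spacing
    # just has to prevent union-merging ambiguity with intergenic regions
    decoys: list[dict] = []
    decoy_centres: dict[str, list[int]] = {}
    decoy_sep = max(2 * cfg.peak_width_max, 1000)
    n_decoys = cfg.n_decoy_peaks if genes else 0  # decoys live inside genes
    for i in range(n_decoys):
        for _try in range(4000):
            g = genes[int(rng.integers(len(genes)))]
            width = int(rng.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
            if g.end - g.start <= width + 2:
                continue
            s = int(rng.integers(g.start, g.end - width))
            e = s + width
            c = (s + e) // 2
            if all(
                abs(c - pc) >= cfg.min_peak_separation for pc in placed.get(g.chrom, ())
            ) and all(abs(c - dc) >= decoy_sep for dc in decoy_centres.get(g.chrom, ())):
                break
        else:
            raise ValueError("infeasible packing: decoys do not fit inside genes")
        decoy_centres.setdefault(g.chrom, []).append(c)
        decoys.append({"name": f"decoy_{i + 1:03d}", "chrom": g.chrom, "start": s, "end": e})

    ivs = [
        Interval(p["chrom"], p["start"], p["end"], name=p["name"])
        for p in planted + background + decoys
    ]
    peaks = RegionSet(ivs).sort()
    truth = {
        "planted_ernas": planted,
        "background_peaks": background,
        "decoy_peaks": decoys,
        "target_genes": sorted({p["target_gene"] for p in planted}),
    }
    return SimulatedGenome(ann, peaks, truth)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with Var = mu + dispersion * mu^2 (Poisson when dispersion ~ 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _true_net_change(
    genome: SimulatedGenome, window: int
) -> dict[str, int]:
    """Per gene: planted gained minus lost eRNAs within +/-window of TSS."""
    net = {g.gene_id: 0 for g in genome.annotation.genes}
    for p in genome.truth["planted_ernas"]:
        centre = (p["start"] + p["end"]) // 2
        for g in genome.annotation.genes:
            if g.chrom == p["chrom"] and abs(g.tss - centre) <= window:
                net[g.gene_id] += p["direction"]
    return net


def simulate_counts(
    cfg: SimConfig,
    genome: SimulatedGenome,
    rng: np.random.Generator | None = None,
) -> SimulatedCounts:
    """Per-sample stranded fragments plus a coupled gene-expression matrix."""
    rng = rng or cfg.rngs()["counts"]
    samples = [f"{COHORT_A}_{i + 1:02d}" for i in range(cfg.n_a)] + [
        f"{COHORT_B}_{i + 1:02d}" for i in range(cfg.n_b)
    ]
    cohorts = [COHORT_A] * cfg.n_a + [COHORT_B] * cfg.n_b
    n_samples = len(samples)

    peaks = list(genome.peaks)
    name_to_iv = {iv.name: iv for iv in peaks}
    quiet_names = {p["name"] for p in genome.truth["background_peaks"] if p["quiet"]}
    planted_by_name = {p["name"]: p for p in genome.truth["planted_ernas"]}

    # per-region per-sample NB means
    is_b = np.array([c == COHORT_B for c in cohorts])
    mult = 2.0 ** cfg.planted_log2fc
    mean_matrix = np.zeros((len(peaks), n_samples))
    for i, iv in enumerate(peaks):
        base = cfg.quiet_mean if iv.name in quiet_names else cfg.nb_mean
        mu = np.full(n_samples, base)
        p = planted_by_name.get(iv.name)
        if p is not None:
            if p["direction"] > 0:
                mu[is_b] = base * mult          # gained from A to B
            else:
                mu[~is_b] = base * mult         # lost from A to B
        mean_matrix[i] = mu
    depth = np.exp(rng.normal(0.0, cfg.depth_sd, size=n_samples))
    scaled = mean_matrix * depth[None, :]
    is_planted = np.array([iv.name in planted_by_name for iv in peaks])
    counts = _nb_draw(rng, scaled, cfg.nb_dispersion)
    counts[is_planted] = _nb_draw(rng, scaled[is_planted], cfg.planted_dispersion)

    # stranded fragments: fixed-length, centred uniformly in the region
    half = cfg.fragment_length // 2
    fragment_sets: list[FragmentSet] = []
    for j, sid in enumerate(samples):
        frags: list[Interval] = []
        for i, iv in enumerate(peaks):
            c = int(counts[i, j])
            if c == 0:
                continue
            centres = rng.integers(iv.start, iv.end, size=c)
            n_plus = rng.binomial(c, cfg.bidirectional_fraction)
            strands = ["+"] * n_plus + ["-"] * (c - n_plus)
            for centre, strand in zip(centres, strands):
                s = max(0, int(centre) - half)
                frags.append(Interval(iv.chrom, s, s + cfg.fragment_length, strand=strand))
        fragment_sets.append(FragmentSet(sid, frags))

    # eRNA signals.  z: pooled standardised FPM (carries the cohort gap);
    # w: within-cohort standardised fluctuations (unit SD, zero cohort mean)
    lib = np.array([fs.library_size for fs in fragment_sets], dtype=float)
    fpm = counts * 1e6 / lib[None, :]
    sd = fpm.std(axis=1)
    z = (fpm - fpm.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    w = np.empty_like(fpm)
    w[:, ~is_b] = fpm[:, ~is_b] - fpm[:, ~is_b].mean(axis=1, keepdims=True)
    w[:, is_b] = fpm[:, is_b] - fpm[:, is_b].mean(axis=1, keepdims=True)
    wsd = w.std(axis=1)
    w = w / np.where(wsd > 0, wsd, 1.0)[:, None]
    name_to_row = {iv.name: i for i, iv in enumerate(peaks)}

    # Gene expression: each eRNA within the net window of a gene's TSS
    # contributes its full cohort-level expression shift (gamma times the
    # realised cohort gap of its standardised signal); the designated
    # target receives the eRNA's complete per-sample signal instead of just
    # the cohort-mean component, so it alone also tracks within-cohort
    # fluctuations.  Every gene's expected log2 shift is therefore
    # gamma * sum of realised per-eRNA gaps -- an exactly uniform slope in
    # its net eRNA change -- while the true target is uniquely identifiable
    # by correlation.
    net = _true_net_change(genome, cfg.net_window)
    genes = genome.annotation.genes
    centre_of = {
        p["name"]: (p["chrom"], (p["start"] + p["end"]) // 2)
        for p in genome.truth["planted_ernas"]
    }
    target_of = {p["name"]: p["target_gene"] for p in genome.truth["planted_ernas"]}
    gap = {
        name: float(z[name_to_row[name], is_b].mean() - z[name_to_row[name], ~is_b].mean())
        for name in centre_of
    }
    block_sign = np.where(is_b, 0.5, -0.5)
    expr = np.zeros((len(genes), n_samples))
    baselines = rng.normal(8.0, 1.0, size=len(genes))
    true_lfc: dict[str, float] = {}
    target_genes = set(target_of.values())
    for gi, g in enumerate(genes):
        noise_sd = (
            cfg.expression_noise_sd
            if g.gene_id in target_genes
            else cfg.background_gene_sd
        )
        row = baselines[gi] + rng.normal(0.0, noise_sd, size=n_samples)
        lfc = 0.0
        for name, (chrom, centre) in centre_of.items():
            if chrom != g.chrom or abs(g.tss - centre) > cfg.net_window:
                continue
            if target_of[name] == g.gene_id:
                row = row + cfg.coupling_gamma * (
                    z[name_to_row[name]] - z[name_to_row[name]].mean()
                )
            else:
                row = row + cfg.coupling_gamma * gap[name] * block_sign
            lfc += cfg.coupling_gamma * gap[name]
        expr[gi] = row
        true_lfc[g.gene_id] = lfc

    gene_expression = pd.DataFrame(expr, index=[g.gene_id for g in genes], columns=samples)
    metadata = pd.DataFrame({"sample_id": samples, "cohort": cohorts})
    truth = dict(genome.truth)
    truth["true_net_change"] = net
    truth["true_gene_log2fc"] = true_lfc
    return SimulatedCounts(fragment_sets, gene_expression, metadata, truth)


def _censor_times(
    rng: np.random.Generator, t: np.ndarray, target_fraction: float
) -> np.ndarray:
    """Uniform(0, q) censoring times with q tuned so the realised censored
    fraction approximates the target."""
    if target_fraction <= 0:
        return np.full_like(t, np.inf)
    u = rng.random(len(t))
    lo, hi = 1e-6, float(t.max()) * 50

    def frac(q: float) -> float:
        return float(np.mean(u * q < t))  # censored iff C < T

    # censored fraction decreases as q grows
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target_fraction:
            lo = mid
        else:
            hi = mid
    return u * (0.5 * (lo + hi))


def simulate_survival(
    cfg: SimConfig,
    expr: pd.DataFrame,
    rng: np.random.Generator | None = None,
    beta: Mapping[str, float] | None = None,
) -> tuple[SurvivalData, dict]:
    """Exponential survival with hazard exp(sum beta_i x_i) on z-scored genes."""
    rng = rng or cfg.rngs()["survival"]
    if beta is None:
        beta = cfg.survival_beta
    if not beta:
        raise ValueError("no survival coefficients configured")
    missing = [g for g in beta if g not in expr.index]
    if missing:
        raise ValueError(f"survival beta on unknown gene(s): {missing}")
    x = expr.loc[list(beta)].to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    xz = (x - mu) / np.where(sd > 0, sd, 1.0)
    lin = np.asarray(list(beta.values())) @ xz
    hazard = cfg.baseline_hazard * np.exp(lin)
    t = rng.exponential(1.0 / hazard)
    c = _censor_times(rng, t, cfg.censoring_fraction)
    event = (t <= c).astype(int)
    obs = np.minimum(t, c)
    obs = np.maximum(obs, 1e-6)
    surv = SurvivalData(obs, event, sample_ids=list(expr.columns))
    truth = {"survival_beta": dict(beta), "censoring_fraction_realised": float(1 - event.mean())}
    return surv, truth


def simulate_survival_cohort(
    seed: int,
    n_samples: int = 500,
    beta: float = 0.7,
    n_null_genes: int = 49,
    censoring_fraction: float = 0.2,
    baseline_hazard: float = 0.02,
) -> tuple[pd.DataFrame, SurvivalData, str]:
    """Standalone survival cohort: one prognostic gene among nulls.

    Expression is standard normal per gene; the hazard is
    baseline * exp(beta * x_signal).  Used for coefficient-recovery and
    screening checks at larger n than the main cohort.
    """
    rng = np.random.default_rng(seed)
    gene_ids = ["SIG001"] + [f"NULL{i + 1:03d}" for i in range(n_null_genes)]
    x = rng.normal(size=(1 + n_null_genes, n_samples))
    expr = pd.DataFrame(x, index=gene_ids, columns=[f"s{i + 1}" for i in range(n_samples)])
    hazard = baseline_hazard * np.exp(beta * x[0])
    t = rng.exponential(1.0 / hazard)
    c = _censor_times(rng, t, censoring_fraction)
    surv = SurvivalData(np.maximum(np.minimum(t, c), 1e-6), (t <= c).astype(int),
                        sample_ids=list(expr.columns))
    return expr, surv, "SIG001"


def simulate_dataset(cfg: SimConfig):
    """Full study: genome, counts/fragments/expression, survival, truth."""
    rngs = cfg.rngs()
    genome = simulate_genome(cfg, rngs["genome"])
    sim = simulate_counts(cfg, genome, rngs["counts"])
    beta = cfg.survival_beta or {
        genome.truth["target_genes"][0]: cfg.default_survival_beta
    }
    surv, surv_truth = simulate_survival(cfg, sim.gene_expression, rngs["survival"], beta)
    truth = dict(sim.truth)
    truth.update(surv_truth)
    return genome, sim, surv, truth


def write_dataset(out_dir: str | os.PathLike, cfg: SimConfig) -> dict:
    """Write the full simulated study as plain-text files.

    Emits genome.gtf, chrom.sizes, peaks_<sample>.bed, fragments_<sample>.bed,
    gene_expr.tsv, meta.tsv, survival.tsv and truth.json.  Per-sample peak
    files are the true peaks with small boundary jitter, so the union-merge
    stage has real work to do.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    genome, sim, surv, truth = simulate_dataset(cfg)
    jitter_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 997]))

    with open(os.path.join(out, "genome.gtf"), "w") as fh:
        for g in genome.annotation.genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\terna_scout_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    with open(os.path.join(out, "chrom.sizes"), "w") as fh:
        for chrom, size in sorted(genome.annotation.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")

    for fs in sim.fragment_sets:
        jit = jitter_rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1, size=(len(genome.peaks), 2))
        ivs = [
            Interval(iv.chrom, max(0, iv.start + int(a)), iv.end + int(b), name=iv.name)
            for iv, (a, b) in zip(genome.peaks, jit)
        ]
        RegionSet(ivs).sort().write_bed(os.path.join(out, f"peaks_{fs.sample_id}.bed"))
        frag_rs = RegionSet(list(fs.fragments)).sort()
        frag_rs.write_bed(os.path.join(out, f"fragments_{fs.sample_id}.bed"))

    sim.gene_expression.rename_axis("gene_id").to_csv(
        os.path.join(out, "gene_expr.tsv"), sep="\t"
    )
    sim.metadata.to_csv(os.path.join(out, "meta.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(os.path.join(out, "survival.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


def match_planted_regions(truth: dict, regions: RegionSet) -> dict[str, str | None]:
    """Map each planted eRNA to the emitted region containing its centre."""
    out: dict[str, str | None] = {}
    region_list = list(regions)
    ids = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in region_list]
    for p in truth["planted_ernas"]:
        centre = (p["start"] + p["end"]) // 2
        hit = None
        for iv, rid in zip(region_list, ids):
            if iv.chrom == p["chrom"] and iv.start <= centre < iv.end:
                hit = rid
                break
        out[p["name"]] = hit
    return out
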