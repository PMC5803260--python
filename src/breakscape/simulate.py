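"""Synthetic genomes, break sites, coverage tracks and qPCR Ct values.

The generator emulates the statistical structure of a restriction-enzyme
DSB-induction experiment (DIvA-style): a genome carries annotated
recognition sites of which only a subset is actually cleaved in cells;
an RNA:DNA-helicase ChIP signal (senataxin) accumulates in a narrow
(1-2 kb) window around cleaved sites in proportion to cleavage efficiency
and local transcription; DRIP (R-loop) signal peaks at TSS/TTS of
expressed genes and, after damage, gains over a ~10 kb window around cut
sites with a sharp central depletion where the helicase acts.  qPCR cycle
thresholds follow Ct = ref - log_E(quantity) + noise.

Every stage draws from its own RNG stream derived from the master seed and
a stage name, so adding a stage never perturbs earlier stages' draws, and
identical configurations give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageTrack, Interval, write_bed, write_chrom_sizes
from .qpcr import CtMeasurement

__all__ = [
    "SimConfig",
    "GenomeModel",
    "SimulationError",
    "simulate_genome",
    "simulate_chip_coverage",
    "simulate_drip_coverage",
    "simulate_qpcr",
    "simulate_resection_experiment",
    "full_scale_config",
]

CHIP_ASSAYS = ("senataxin", "polII_total", "polII_S2P", "generic")
CONDITIONS = ("undamaged", "damaged")


class SimulationError(ValueError):
    pass


def _rng(seed: int, *stage: str) -> np.random.Generator:
    """One RNG stream per (seed, stage-name) pair, platform independent."""
    tags = [zlib.crc32(s.encode()) for s in stage]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults are scaled for seconds-level runs (one 2 Mb chromosome,
    60 genes, 120 annotated sites of which 20 cut) while preserving the
    geometry of the full-scale system; :func:`full_scale_config` gives the
    ~1200-site / 80-cut preset.
    """

    # genome geometry
    n_chromosomes: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (5_000, 30_000)
    # transcription: log-normal expression, a fraction of genes silent
    expression_log_mean: float = 1.0
    expression_log_sd: float = 1.0
    silent_gene_fraction: float = 0.3
    # break sites
    n_sites: int = 120
    n_cut: int = 20
    cleavage_efficiency_range: tuple[float, float] = (0.4, 1.0)
    cut_in_active_fraction: float = 0.8
    min_site_spacing: int = 0
    edge_margin: int = 20_000
    # ChIP phenomenology
    enrichment_halfwidth: int = 1_000
    chip_enrichment: float = 1.0
    polII_amp: float = 0.3
    # DRIP phenomenology
    dsb_gain_halfwidth: int = 5_000
    depletion_halfwidth: int = 1_000
    drip_gain: float = 2.0
    depletion_depth: float = 0.8
    senataxin_activity: float = 1.0
    drip_tss_amp: float = 2.0
    drip_tss_halfwidth: int = 750
    drip_body_amp: float = 0.5
    body_loss: float = 0.5
    silent_gain_fraction: float = 0.1
    silent_gain_scale: float = 0.3
    # signal model
    background_rate: float = 0.5
    peak_shape: str = "boxcar"  # or "gaussian"
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length <= 0:
            raise SimulationError("need >=1 chromosome of positive length")
        if self.n_cut > self.n_sites:
            raise SimulationError(
                f"n_cut ({self.n_cut}) exceeds n_sites ({self.n_sites})"
            )
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise SimulationError(f"bad gene_length_range {self.gene_length_range}")
        per_chrom = -(-self.n_genes // self.n_chromosomes)
        if per_chrom * hi > self.chrom_length - 2 * self.edge_margin:
            raise SimulationError(
                "total gene length may exceed chromosome length: "
                f"{per_chrom} genes x {hi} bp on {self.chrom_length} bp"
            )
        for hw in (self.enrichment_halfwidth, self.dsb_gain_halfwidth,
                   self.depletion_halfwidth):
            if not (0 < hw < self.chrom_length / 2):
                raise SimulationError(f"halfwidth {hw} out of range")
        elo, ehi = self.cleavage_efficiency_range
        if not (0 <= elo <= ehi <= 1):
            raise SimulationError(
                f"cleavage_efficiency_range {self.cleavage_efficiency_range} "
                "must lie in [0,1]"
            )
        if self.peak_shape not in ("boxcar", "gaussian"):
            raise SimulationError(f"unknown peak_shape {self.peak_shape!r}")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise SimulationError(f"unknown noise_model {self.noise_model!r}")
        if self.background_rate < 0:
            raise SimulationError("background_rate must be >= 0")


def full_scale_config(total_sites: int = 1211, **overrides) -> SimConfig:
    """Full-scale preset: ~1200 annotated sites, 80 cut, 4 chromosomes.

    The source annotation counts are internally inconsistent (1211 annotated
    vs 80 cut + 1139 uncut = 1219), so both totals are accepted here and
    neither is privileged.
    """
    if total_sites not in (1211, 1219):
        raise SimulationError("total_sites preset must be 1211 or 1219")
    base = dict(
        n_chromosomes=4,
        chrom_length=3_000_000,
        n_genes=280,
        n_sites=total_sites,
        n_cut=80,
        edge_margin=10_000,
    )
    base.update(overrides)
    return SimConfig(**base)


def calibration_config(seed: int, **overrides) -> SimConfig:
    """Design for null-calibration and power studies of the cut/uncut test.

    Sites are spaced at least 2.5 kb apart so that +-1 kb quantification
    windows are disjoint and per-site signals independent — the sampling
    assumption of the rank test being calibrated.  All genes are expressed
    so every cut site can carry the configured effect.
    """
    base = dict(chrom_length=400_000, n_genes=10,
                gene_length_range=(8_000, 15_000), silent_gene_fraction=0.0,
                n_sites=40, n_cut=10, min_site_spacing=2_500,
                edge_margin=8_000, seed=seed)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class GenomeModel:
    """Chromosomes, expressed genes and annotated break sites.

    ``genes``: DataFrame (name, chrom, start, end, strand, expression).
    ``sites``: DataFrame (site_id, chrom, position, cut, cleavage_efficiency),
    ordered by (chrom, position).  Exactly ``config.n_cut`` sites carry the
    cut flag; uncut sites have cleavage efficiency 0.
    """

    chromosomes: dict[str, int]
    genes: pd.DataFrame
    sites: pd.DataFrame
    config: SimConfig

    def expression_at(self, chrom: str, position: int) -> float:
        """Expression of the gene containing a position (0 if intergenic)."""
        g = self.genes
        hit = g[(g["chrom"] == chrom) & (g["start"] <= position)
                & (position < g["end"])]
        return float(hit["expression"].iloc[0]) if len(hit) else 0.0

    def write(self, outdir) -> None:
        """chrom.sizes + genes.bed (BED6 + expression) + sites.bed.

        Site BED score = cleavage efficiency x 1000, name = site id.
        """
        import os

        write_chrom_sizes(self.chromosomes, os.path.join(outdir, "genome.chrom.sizes"))
        with open(os.path.join(outdir, "genes.bed"), "w") as fh:
            for _, g in self.genes.sort_values(["chrom", "start"]).iterrows():
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g['name']}\t0\t{g.strand}"
                    f"\t{g.expression:.6g}\n"
                )
        ivs = [
            Interval(s.chrom, int(s.position), int(s.position) + 1,
                     name=s.site_id, score=round(s.cleavage_efficiency * 1000),
                     strand=".")
            for _, s in self.sites.iterrows()
        ]
        write_bed(ivs, os.path.join(outdir, "sites.bed"))


def simulate_genome(config: SimConfig) -> GenomeModel:
    """Place non-overlapping genes and annotated break sites on chromosomes.

    A ``cut_in_active_fraction`` of cut sites lands inside expressed genes,
    the rest in intergenic or silent territory, emulating the observation
    that cleaved recognition sites fall both in active and inactive loci.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _rng(config.seed, "genome")
    chroms = {f"chr{i + 1}": config.chrom_length
              for i in range(config.n_chromosomes)}
    chrom_names = list(chroms)

    # --- genes: sequential placement with random gaps, per chromosome
    gene_rows = []
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    for ci, idx in enumerate(per_chrom):
        n = len(idx)
        if n == 0:
            continue
        chrom = chrom_names[ci]
        lo, hi = config.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=n)
        usable = config.chrom_length - 2 * config.edge_margin
        slack = usable - int(lengths.sum())
        if slack < 0:
            raise SimulationError(
                f"genes do not fit on {chrom}: need {lengths.sum()} of {usable} bp"
            )
        # n+1 random gaps summing to the slack
        gaps = np.floor(np.sort(rng.uniform(0, slack, size=n))).astype(int)
        gaps = np.diff(np.concatenate(([0], gaps, [slack])))
        pos = config.edge_margin
        for k in range(n):
            pos += int(gaps[k])
            gene_rows.append(
                dict(name=f"gene_{idx[k] + 1:04d}", chrom=chrom, start=pos,
                     end=pos + int(lengths[k]),
                     strand="+" if rng.random() < 0.5 else "-")
            )
            pos += int(lengths[k])
    genes = pd.DataFrame(gene_rows)

    expr = rng.lognormal(config.expression_log_mean, config.expression_log_sd,
                         size=len(genes))
    silent = rng.random(len(genes)) < config.silent_gene_fraction
    expr[silent] = 0.0
    genes["expression"] = expr

    # --- break sites
    active = genes[genes["expression"] > 0]
    n_cut_active = int(round(config.n_cut * config.cut_in_active_fraction))
    n_cut_active = min(n_cut_active, config.n_cut) if len(active) else 0
    taken: set[tuple[str, int]] = set()
    site_rows = []

    def _place(chrom: str, position: int, cut: bool):
        key = (chrom, position)
        if key in taken:
            return False
        if config.min_site_spacing > 0 and any(
            c == chrom and abs(p - position) < config.min_site_spacing
            for c, p in taken
        ):
            return False
        taken.add(key)
        site_rows.append(dict(chrom=chrom, position=position, cut=cut))
        return True

    for _ in range(n_cut_active):
        for _attempt in range(10_000):
            g = active.iloc[int(rng.integers(len(active)))]
            p = int(rng.integers(g.start, g.end))
            if (config.edge_margin <= p < config.chrom_length - config.edge_margin
                    and _place(g.chrom, p, True)):
                break
        else:
            raise SimulationError(
                "could not place cut site inside an active gene; genome too "
                f"small for spacing {config.min_site_spacing}"
            )

    def _place_outside_active(cut: bool):
        for _ in range(10000):
            chrom = chrom_names[int(rng.integers(config.n_chromosomes))]
            p = int(rng.integers(config.edge_margin,
                                 config.chrom_length - config.edge_margin))
            g = genes[(genes["chrom"] == chrom) & (genes["start"] <= p)
                      & (p < genes["end"])]
            in_active = len(g) > 0 and float(g["expression"].iloc[0]) > 0
            if not in_active and _place(chrom, p, cut):
                return
        raise SimulationError("could not place site outside active genes")

    for _ in range(config.n_cut - n_cut_active):
        _place_outside_active(True)
    # uncut sites anywhere (active or not), uniform
    placed = attempts = 0
    max_attempts = 1000 * config.n_sites
    while placed < config.n_sites - config.n_cut:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                "could not place all sites; genome too small for "
                f"n_sites={config.n_sites} at spacing {config.min_site_spacing}"
            )
        chrom = chrom_names[int(rng.integers(config.n_chromosomes))]
        p = int(rng.integers(config.edge_margin,
                             config.chrom_length - config.edge_margin))
        if _place(chrom, p, False):
            placed += 1

    sites = pd.DataFrame(site_rows).sort_values(["chrom", "position"])
    sites = sites.reset_index(drop=True)
    elo, ehi = config.cleavage_efficiency_range
    eff = np.zeros(len(sites))
    cut_mask = sites["cut"].to_numpy()
    eff[cut_mask] = _rng(config.seed, "cleavage").uniform(elo, ehi, cut_mask.sum())
    sites["cleavage_efficiency"] = eff
    sites.insert(0, "site_id", [f"DSB_{i + 1:04d}" for i in range(len(sites))])
    return GenomeModel(chromosomes=chroms, genes=genes, sites=sites, config=config)


def _peak(arr: np.ndarray, center: int, halfwidth: int, amplitude: float,
          shape: str) -> None:
    """Add a symmetric peak in place; boxcar or Gaussian (sigma = hw/2)."""
    n = arr.size
    if shape == "boxcar":
        lo = max(0, center - halfwidth)
        hi = min(n, center + halfwidth)
        arr[lo:hi] += amplitude
    else:
        sigma = halfwidth / 2.0
        lo = max(0, center - 4 * halfwidth)
        hi = min(n, center + 4 * halfwidth)
        x = np.arange(lo, hi) - center
        arr[lo:hi] += amplitude * np.exp(-0.5 * (x / sigma) ** 2)


def _apply_noise(expected: dict[str, np.ndarray], config: SimConfig,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    if config.noise_model == "none":
        return expected
    out = {}
    for chrom, lam in expected.items():
        if config.noise_model == "poisson":
            out[chrom] = rng.poisson(lam).astype(float)
        else:  # gaussian with variance tracking the mean, clipped at 0
            sd = config.noise_scale * np.sqrt(np.maximum(lam, 1e-12))
            out[chrom] = np.clip(lam + rng.normal(0.0, 1.0, lam.size) * sd, 0.0, None)
    return out


def _gene_index(genome: GenomeModel):
    """(chrom, start, end, strand, expression) tuples for fast iteration."""
    return list(genome.genes[["chrom", "start", "end", "strand",
                              "expression"]].itertuples(index=False, name=None))


def simulate_chip_coverage(genome: GenomeModel, assay: str,
                           condition: str) -> CoverageTrack:
    """ChIP coverage for one assay/condition.

    * ``senataxin`` + ``damaged``: background plus, at every cut site, a peak
      of half-width ``enrichment_halfwidth`` with amplitude
      ``chip_enrichment x cleavage_efficiency x expression`` of the
      containing gene (zero at intergenic/silent sites).
    * ``senataxin`` + ``undamaged``: background only.
    * ``polII_total`` / ``polII_S2P``: gene-body signal proportional to
      expression, condition independent.
    * ``generic``: background only in both conditions (null assay).
    """
    if assay not in CHIP_ASSAYS:
        raise SimulationError(f"unknown assay {assay!r}; choose from {CHIP_ASSAYS}")
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}")
    cfg = genome.config
    expected = {c: np.full(n, float(cfg.background_rate))
                for c, n in genome.chromosomes.items()}

    if assay in ("polII_total", "polII_S2P"):
        for chrom, start, end, _strand, expr in _gene_index(genome):
            if expr > 0:
                expected[chrom][start:end] += cfg.polII_amp * expr
    elif assay == "senataxin" and condition == "damaged":
        for s in genome.sites.itertuples():
            if not s.cut:
                continue
            expr = genome.expression_at(s.chrom, s.position)
            amp = cfg.chip_enrichment * s.cleavage_efficiency * expr
            if amp > 0:
                _peak(expected[s.chrom], int(s.position),
                      cfg.enrichment_halfwidth, amp, cfg.peak_shape)
    # senataxin/undamaged and generic: background only

    rng = _rng(cfg.seed, "chip", assay, condition)
    values = _apply_noise(expected, cfg, rng)
    track = CoverageTrack(values=values, label=f"{assay}_{condition}")
    track.library_size = track.total()
    return track


def simulate_drip_coverage(genome: GenomeModel, condition: str,
                           senataxin_activity: float | None = None) -> CoverageTrack:
    """DRIP (RNA:DNA hybrid) coverage.

    Baseline (both conditions): background, gene-body signal and TSS/TTS
    peaks on expressed genes, all proportional to expression.  The damaged
    condition multiplies, per cut site in an expressed gene: a
    ``drip_gain``-fold gain over +-``dsb_gain_halfwidth``; a central
    depletion factor ``1 - activity x depletion_depth`` over
    +-``depletion_halfwidth`` (``activity`` = 0 emulates helicase
    knockdown); and a ``body_loss`` factor on the damaged gene body.  A
    ``silent_gain_fraction`` minority of silent cut sites receives a
    low-amplitude gain.
    """
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}")
    cfg = genome.config
    activity = cfg.senataxin_activity if senataxin_activity is None \
        else float(senataxin_activity)
    if not (0.0 <= activity <= 1.0):
        raise SimulationError("senataxin_activity must be in [0, 1]")

    baseline = {c: np.full(n, float(cfg.background_rate))
                for c, n in genome.chromosomes.items()}
    for chrom, start, end, strand, expr in _gene_index(genome):
        if expr <= 0:
            continue
        baseline[chrom][start:end] += cfg.drip_body_amp * expr
        tss, tts = (start, end - 1) if strand == "+" else (end - 1, start)
        _peak(baseline[chrom], tss, cfg.drip_tss_halfwidth,
              cfg.drip_tss_amp * expr, cfg.peak_shape)
        _peak(baseline[chrom], tts, cfg.drip_tss_halfwidth,
              cfg.drip_tss_amp * expr, cfg.peak_shape)

    if condition == "damaged":
        factor = {c: np.ones(n) for c, n in genome.chromosomes.items()}
        cut = genome.sites[genome.sites["cut"]]
        silent_rng = _rng(cfg.seed, "drip-silent")
        for s in cut.itertuples():
            arr = factor[s.chrom]
            p = int(s.position)
            expr = genome.expression_at(s.chrom, p)
            glo = max(0, p - cfg.dsb_gain_halfwidth)
            ghi = min(arr.size, p + cfg.dsb_gain_halfwidth)
            if expr > 0:
                arr[glo:ghi] *= cfg.drip_gain
                dlo = max(0, p - cfg.depletion_halfwidth)
                dhi = min(arr.size, p + cfg.depletion_halfwidth)
                arr[dlo:dhi] *= max(0.0, 1.0 - activity * cfg.depletion_depth)
                g = genome.genes
                host = g[(g["chrom"] == s.chrom) & (g["start"] <= p)
                         & (p < g["end"])].iloc[0]
                # hybrid loss across the damaged gene body, outside the
                # break-proximal gain window where accumulation dominates
                for lo_b, hi_b in ((host.start, max(host.start, glo)),
                                   (min(host.end, ghi), host.end)):
                    if hi_b > lo_b:
                        arr[lo_b:hi_b] *= cfg.body_loss
            elif silent_rng.random() < cfg.silent_gain_fraction:
                arr[glo:ghi] *= 1.0 + (cfg.drip_gain - 1.0) * cfg.silent_gain_scale
        expected = {c: baseline[c] * factor[c] for c in baseline}
    else:
        expected = baseline

    rng = _rng(cfg.seed, "drip", condition, f"act={activity:g}")
    values = _apply_noise(expected, cfg, rng)
    track = CoverageTrack(values=values, label=f"drip_{condition}")
    track.library_size = track.total()
    return track


def simulate_qpcr(true_quantities, reference_ct: float = 25.0,
                  efficiency: float = 2.0, noise_sd: float = 0.0,
                  seed: int = 0, sample: str = "sim", target: str = "amplicon",
                  condition: str = "na") -> list[CtMeasurement]:
    """Ct values for known template quantities.

    Ct = reference_ct - log_efficiency(quantity) + N(0, noise_sd): doubling
    a quantity lowers Ct by one cycle at perfect efficiency (E = 2).
    """
    q = np.asarray(true_quantities, dtype=float)
    if (q <= 0).any():
        raise SimulationError("quantities must be positive (Ct undefined at 0)")
    if not (1.0 < efficiency <= 2.0):
        raise SimulationError(f"efficiency must be in (1, 2], got {efficiency}")
    rng = _rng(seed, "qpcr", sample, target, condition)
    noise = rng.normal(0.0, noise_sd, q.size) if noise_sd > 0 else np.zeros(q.size)
    cts = reference_ct - np.log(q) / np.log(efficiency) + noise
    return [
        CtMeasurement(sample=sample, target=target, condition=condition,
                      replicate=i + 1, ct=float(ct))
        for i, ct in enumerate(cts)
    ]


def simulate_resection_experiment(true_ssdna_fraction: float,
                                  noise_sd: float = 0.0, base_ct: float = 25.0,
                                  seed: int = 0, sample: str = "sim",
                                  target: str = "DSB_probe"
                                  ) -> tuple[CtMeasurement, CtMeasurement]:
    """(digested, undigested) Ct pair whose ssDNA% readout is the truth.

    Inverts the differential-digest readout
    ssDNA% = 1 / (2^(dCt - 1) + 0.5) x 100 with dCt = Ct_dig - Ct_undig:
    dCt = 1 + log2(1/f - 0.5) for a true single-stranded fraction f, so at
    zero noise the round trip through the assay formula is exact.
    """
    f = float(true_ssdna_fraction)
    if not (0.0 < f <= 1.0):
        raise SimulationError(f"ssDNA fraction must be in (0, 1], got {f}")
    dct = 1.0 + np.log2(1.0 / f - 0.5)
    rng = _rng(seed, "resection", sample, target)
    eps = rng.normal(0.0, noise_sd, 2) if noise_sd > 0 else np.zeros(2)
    undig = CtMeasurement(sample=sample, target=target, condition="undigested",
                          replicate=1, ct=float(base_ct + eps[0]))
    dig = CtMeasurement(sample=sample, target=target, condition="digested",
                        replicate=1, ct=float(base_ct + dct + eps[1]))
    return dig, undig
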