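"""Synthetic data generator with planted, parameterised structure.

Generates a complete toy input bundle — genome, TSS catalogue, per-TF
signal tracks, TRANSFAC matrices, labels, expression values, a
protein-interaction graph and knockdown gene sets — in which every effect
the pipeline is meant to detect is planted explicitly and recorded in a
truth table:

* informative TFs bind cell-cycle promoters with boosted odds and deposit
  Gaussian-shaped peaks near their TSSs on a lognormal background;
* informative motifs are inserted into positive promoters at a higher
  rate than into negative promoters;
* an expression confounder raises both the expression of positives and
  the binding odds of *every* TF, mimicking the expression bias of
  microarray-derived training labels;
* phase-preferential TFs bind genes peaking in their preferred
  cell-cycle phase with extra odds.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cyclescan.classifier import PhaseBinSpec
from cyclescan.genomic_io import (
    BASES,
    PfmMatrix,
    SignalTrack,
    TssRecord,
    write_bedgraph,
    write_cutoffs,
    write_fasta,
    write_transfac,
    write_tss_bed,
)
from cyclescan.motif import _encode, _minmax, reverse_complement


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Effect sizes (``tf_effect``, plant rates, confounder) are odds
    multipliers / probabilities of the planted structure; geometry fields
    control the toy genome.  All rates live in [0, 1].
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {"protein_coding": 850, "lincRNA": 100, "pseudogene": 50}
    )
    frac_cell_cycle: float = 0.03
    # TF binding structure
    n_tfs: int = 20
    n_informative_tfs: int = 8
    tf_effect: float = 4.0  # odds multiplier for binding a positive promoter
    baseline_bind_prob: float = 0.15
    tf_phase_preference: Mapping[str, str] | None = None  # tf id -> phase name
    phase_boost: float = 4.0
    # peak geometry and background noise
    peak_height: float = 20.0
    peak_sd: float = 100.0
    peak_offset_sd: float = 900.0
    peak_height_sigma: float = 0.5  # lognormal sd of per-site strength
    background_sigma: float = 0.5  # lognormal(0, sigma) per background node
    background_bin: int = 25
    # motif structure
    n_motifs: int = 20
    n_informative_motifs: int = 5
    motif_plant_rate_pos: float = 0.4  # pi+
    motif_plant_rate_neg: float = 0.1  # pi-
    motif_length: int = 10
    motif_consensus_count: float = 17.0  # of 20 observations per position
    # expression confounder
    expression_confounder: float = 1.0  # log-odds of binding per expression unit
    expression_shift: float = 1.0  # mean expression excess of positives
    # external validation data
    knockdown_overlap_rate: float = 0.5
    n_knockdown: int = 100
    ppi_mean_degree: float = 4.0
    ppi_cc_boost: float = 3.0
    # geometry contract
    tip_half_width: int = 5000
    promoter_upstream: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "frac_cell_cycle",
            "baseline_bind_prob",
            "motif_plant_rate_pos",
            "motif_plant_rate_neg",
            "knockdown_overlap_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chrom_length < 2 * self.tip_half_width:
            raise ValueError("chrom_length must be at least twice the TIP half-width")
        if self.n_informative_tfs > self.n_tfs:
            raise ValueError("more informative TFs than TFs")
        if self.n_informative_motifs > self.n_motifs:
            raise ValueError("more informative motifs than motifs")

    @property
    def total_genes(self) -> int:
        return sum(self.n_genes.values())


@dataclass
class SimBundle:
    """Everything one simulated study produces, plus the planted truth."""

    config: SimConfig
    chrom_lengths: dict[str, int]
    genome: dict[str, str]
    tss: list[TssRecord]
    tracks: dict[str, SignalTrack]
    matrices: list[PfmMatrix]
    labels: dict[str, int]
    peak_times: dict[str, float]
    expression: dict[str, float]
    informative_tfs: list[str]
    informative_motifs: list[str]
    binding: pd.DataFrame  # genes x tfs, planted bound indicator
    planted_motifs: pd.DataFrame  # genes x motifs, planted instance indicator
    ppi_edges: list[tuple[str, str]]
    knockdown_sets: dict[str, set[str]]
    truth: pd.DataFrame


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[TssRecord]:
    """Evenly spaced, jittered TSSs across chromosomes with random strands."""
    margin = max(cfg.promoter_upstream + 100, 1500)
    total = cfg.total_genes
    per_chrom = [total // cfg.n_chroms + (1 if i < total % cfg.n_chroms else 0) for i in range(cfg.n_chroms)]
    usable = cfg.chrom_length - 2 * margin
    categories: list[str] = []
    for cat, n in cfg.n_genes.items():
        categories.extend([cat] * n)
    cat_order = rng.permutation(len(categories))
    records: list[TssRecord] = []
    gidx = 0
    for ci, n_on in enumerate(per_chrom):
        if n_on == 0:
            continue
        spacing = usable / n_on
        if spacing < 2 * cfg.promoter_upstream + 200:
            raise ValueError(
                "infeasible geometry: genes too dense for promoter windows "
                f"(spacing {spacing:.0f} bp)"
            )
        chrom = f"chr{ci + 1}"
        for j in range(n_on):
            base = margin + j * spacing + spacing / 2
            jitter = rng.uniform(-spacing / 5, spacing / 5)
            pos = int(np.clip(base + jitter, margin, cfg.chrom_length - margin - 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            records.append(
                TssRecord(
                    chrom,
                    pos,
                    strand,
                    f"g{gidx:04d}",
                    category=categories[cat_order[gidx]],
                )
            )
            gidx += 1
    return records


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_genome(cfg: SimConfig, rng: np.random.Generator) -> dict[str, bytearray]:
    out = {}
    for ci in range(cfg.n_chroms):
        arr = rng.integers(0, 4, size=cfg.chrom_length)
        out[f"chr{ci + 1}"] = bytearray(_BASE_BYTES[arr].tobytes())
    return out


def _random_pfm(motif_id: str, cfg: SimConfig, rng: np.random.Generator) -> PfmMatrix:
    L = cfg.motif_length
    consensus = rng.integers(0, 4, size=L)
    total = 20.0
    other = (total - cfg.motif_consensus_count) / 3.0
    counts = np.full((L, 4), other)
    counts[np.arange(L), consensus] = cfg.motif_consensus_count
    return PfmMatrix(motif_id, counts)


def _sample_instances(matrix: PfmMatrix, n: int, rng: np.random.Generator) -> list[str]:
    f = matrix.counts / matrix.counts.sum(axis=1, keepdims=True)
    cols = np.stack([rng.choice(4, size=n, p=f[i]) for i in range(matrix.length)], axis=1)
    return ["".join(BASES[b] for b in row) for row in cols]


def _instance_scores(matrix: PfmMatrix, instances: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(mss, css) of exact-length instances under the matrix's scoring."""
    f = matrix.frequencies()
    info = matrix.information()
    psv = info[:, None] * f
    lo, hi = _minmax(psv)
    core = slice(matrix.core_start, matrix.core_start + matrix.core_len)
    clo, chi = _minmax(psv[core])
    mss, css = [], []
    for inst in instances:
        enc = _encode(inst)
        raw = psv[np.arange(matrix.length), enc].sum()
        raw_core = psv[core][np.arange(matrix.core_len), enc[core]].sum()
        mss.append((raw - lo) / (hi - lo) if hi > lo else 1.0)
        css.append((raw_core - clo) / (chi - clo) if chi > clo else 1.0)
    return np.array(mss), np.array(css)


def calibrate_cutoffs(
    matrix: PfmMatrix,
    rng: np.random.Generator,
    n_samples: int = 300,
    mss_quantile: float = 0.25,
    css_quantile: float = 0.10,
    mss_floor: float = 0.75,
    css_floor: float = 0.50,
) -> tuple[float, float]:
    """Matrix-specific scan cutoffs from the matrix's own site distribution.

    In the spirit of matrix-specific MATCH cutoff profiles, the MSS cutoff
    is set at a lower quantile of the score distribution of sites sampled
    from the matrix itself (so a controlled fraction of genuine sites
    falls below it, trading sensitivity for specificity), floored to keep
    random-sequence matches rare.
    """
    mss, css = _instance_scores(matrix, _sample_instances(matrix, n_samples, rng))
    return (
        float(min(0.999, max(mss_floor, np.quantile(mss, mss_quantile)))),
        float(min(0.999, max(css_floor, np.quantile(css, css_quantile)))),
    )


def plant_signal_track(
    tss: Sequence[TssRecord],
    bound_strength: Mapping[str, float],
    chrom_lengths: Mapping[str, int],
    seed: int | None = 0,
    peak_sd: float = 100.0,
    peak_offset_sd: float = 900.0,
    background_sigma: float = 0.5,
    background_bin: int = 25,
) -> SignalTrack:
    """One TF's signal track: Gaussian peaks at bound TSSs over noise.

    ``bound_strength`` maps gene id -> peak amplitude (unbound genes are
    simply absent).  Each bound gene gets one Gaussian peak of the given
    amplitude and sd, centred at a normally distributed offset from its
    TSS.  The background is lognormal noise sampled at ``background_bin``
    bp nodes and linearly interpolated; the stored track is binned back to
    that resolution (bedGraph-style).  ``background_sigma = 0`` with an
    empty ``bound_strength`` yields a flat unit background.
    """
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_nodes = length // background_bin + 2
        if background_sigma > 0:
            nodes = rng.lognormal(0.0, background_sigma, size=n_nodes)
        else:
            nodes = np.ones(n_nodes)
        x = np.arange(length, dtype=np.float64)
        arrays[chrom] = np.interp(x, np.arange(n_nodes) * background_bin, nodes)
    for r in tss:
        if r.gene_id not in bound_strength:
            continue
        amp = bound_strength[r.gene_id]
        if amp <= 0:
            continue
        center = r.pos + rng.normal(0.0, peak_offset_sd)
        half = int(4 * peak_sd)
        a = max(0, int(center) - half)
        b = min(chrom_lengths[r.chrom], int(center) + half + 1)
        if b <= a:
            continue
        x = np.arange(a, b, dtype=np.float64)
        arrays[r.chrom][a:b] += amp * np.exp(-((x - center) ** 2) / (2 * peak_sd**2))
    # bin to background_bin resolution for a realistic sparse representation
    binned: dict[str, np.ndarray] = {}
    for chrom, arr in arrays.items():
        n = len(arr)
        nb = n // background_bin
        head = arr[: nb * background_bin].reshape(nb, background_bin).mean(axis=1)
        out = np.repeat(head, background_bin)
        if n > nb * background_bin:
            tail = arr[nb * background_bin :].mean()
            out = np.concatenate([out, np.full(n - nb * background_bin, tail)])
        binned[chrom] = out
    return SignalTrack.from_dense(binned, chrom_lengths)


def plant_promoter_motifs(
    sequences: Mapping[str, str],
    matrix: PfmMatrix,
    plant_in: Sequence[str],
    seed: int | None = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Insert one sampled motif instance into each selected promoter.

    Instances are sampled from the matrix's frequency distribution
    (consensus-like, not exact consensus) and spliced in at a uniform
    offset.  Returns the updated sequences and the insertion offsets.
    """
    rng = np.random.default_rng(seed)
    seqs = dict(sequences)
    offsets: dict[str, int] = {}
    L = matrix.length
    for gene in plant_in:
        seq = seqs[gene]
        if len(seq) < L:
            continue
        inst = _sample_instances(matrix, 1, rng)[0]
        off = int(rng.integers(0, len(seq) - L + 1))
        seqs[gene] = seq[:off] + inst + seq[off + L :]
        offsets[gene] = off
    return seqs, offsets


def _extract_promoter(genome: Mapping[str, bytearray], r: TssRecord, upstream: int) -> str:
    """Promoter sequence (5'->3' of the gene) from a bytearray genome."""
    contig = genome[r.chrom]
    if r.strand == "+":
        return contig[max(0, r.pos - upstream) : r.pos].decode()
    return reverse_complement(contig[r.pos + 1 : r.pos + 1 + upstream].decode())


def _splice_promoter(genome: dict[str, bytearray], r: TssRecord, promoter: str) -> None:
    """Write a promoter sequence back into the genome in place, respecting strand."""
    if r.strand == "+":
        genome[r.chrom][r.pos - len(promoter) : r.pos] = promoter.encode()
    else:
        rc = reverse_complement(promoter).encode()
        genome[r.chrom][r.pos + 1 : r.pos + 1 + len(rc)] = rc


def simulate(config: SimConfig) -> SimBundle:
    """Generate one complete synthetic study bundle from the config seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom_lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    genome = _random_genome(cfg, rng)
    placed = _place_genes(cfg, rng)

    # labels and planted gene-level attributes
    labels: dict[str, int] = {}
    peak_times: dict[str, float] = {}
    for cat in cfg.n_genes:
        members = [r for r in placed if r.category == cat]
        n_cc = int(round(cfg.frac_cell_cycle * len(members)))
        cc_idx = set(rng.choice(len(members), size=n_cc, replace=False).tolist()) if n_cc else set()
        for i, r in enumerate(members):
            labels[r.gene_id] = 1 if i in cc_idx else 0
            if i in cc_idx:
                peak_times[r.gene_id] = float(rng.uniform(0.0, 100.0))
    expression = {
        r.gene_id: float(rng.normal(0.0, 1.0) + cfg.expression_shift * labels[r.gene_id])
        for r in placed
    }
    tss = [
        replace(
            r,
            label="cell_cycle" if labels[r.gene_id] else "non_cell_cycle",
            peak_time=peak_times.get(r.gene_id),
            expression=expression[r.gene_id],
        )
        for r in placed
    ]

    # TF binding and signal tracks
    tf_ids = [f"TF{i + 1:02d}" for i in range(cfg.n_tfs)]
    informative_tfs = tf_ids[: cfg.n_informative_tfs]
    bins = PhaseBinSpec()
    base_logit = _logit(min(max(cfg.baseline_bind_prob, 1e-6), 1 - 1e-6))
    bound = pd.DataFrame(False, index=[r.gene_id for r in tss], columns=tf_ids)
    tracks: dict[str, SignalTrack] = {}
    for tf in tf_ids:
        logits = np.full(len(tss), base_logit)
        for i, r in enumerate(tss):
            y = labels[r.gene_id]
            if tf in informative_tfs and y == 1:
                logits[i] += math.log(cfg.tf_effect)
            pref = (cfg.tf_phase_preference or {}).get(tf)
            if pref and y == 1 and r.gene_id in peak_times:
                if pref in bins.phases_of(peak_times[r.gene_id]):
                    logits[i] += math.log(cfg.phase_boost)
            logits[i] += cfg.expression_confounder * expression[r.gene_id]
        p_bound = 1.0 / (1.0 + np.exp(-logits))
        is_bound = rng.uniform(size=len(tss)) < p_bound
        bound[tf] = is_bound
        strengths = {
            r.gene_id: cfg.peak_height * float(rng.lognormal(0.0, cfg.peak_height_sigma))
            for i, r in enumerate(tss)
            if is_bound[i]
        }
        tracks[tf] = plant_signal_track(
            tss,
            strengths,
            chrom_lengths,
            seed=int(rng.integers(0, 2**31 - 1)),
            peak_sd=cfg.peak_sd,
            peak_offset_sd=cfg.peak_offset_sd,
            background_sigma=cfg.background_sigma,
            background_bin=cfg.background_bin,
        )

    # motifs: matrices, calibrated cutoffs, planted promoter instances
    motif_ids = [f"M{i + 1:03d}" for i in range(cfg.n_motifs)]
    informative_motifs = motif_ids[: cfg.n_informative_motifs]
    matrices: list[PfmMatrix] = []
    for mid in motif_ids:
        m = _random_pfm(mid, cfg, rng)
        m.cutoff_mss, m.cutoff_css = calibrate_cutoffs(m, rng)
        matrices.append(m)
    promoters = {r.gene_id: _extract_promoter(genome, r, cfg.promoter_upstream) for r in tss}
    planted = pd.DataFrame(0, index=[r.gene_id for r in tss], columns=motif_ids)
    y_arr = np.array([labels[r.gene_id] for r in tss])
    for m in matrices:
        if m.motif_id not in informative_motifs:
            continue
        rates = np.where(y_arr == 1, cfg.motif_plant_rate_pos, cfg.motif_plant_rate_neg)
        draws = rng.uniform(size=len(tss))
        chosen = [r.gene_id for i, r in enumerate(tss) if draws[i] < rates[i]]
        promoters, offsets = plant_promoter_motifs(
            promoters, m, chosen, seed=int(rng.integers(0, 2**31 - 1))
        )
        planted.loc[list(offsets), m.motif_id] = 1
    for r in tss:
        _splice_promoter(genome, r, promoters[r.gene_id])

    # protein-interaction graph with planted cell-cycle assortativity
    gene_ids = [r.gene_id for r in tss]
    y = np.array([labels[g] for g in gene_ids])
    n = len(gene_ids)
    p_base = min(1.0, cfg.ppi_mean_degree / max(1, n - 1))
    iu, ju = np.triu_indices(n, k=1)
    boost = cfg.ppi_cc_boost ** (y[iu] + y[ju]).astype(float)
    p_edge = np.minimum(1.0, p_base * boost)
    keep = rng.uniform(size=len(iu)) < p_edge
    ppi_edges = [(gene_ids[a], gene_ids[b]) for a, b in zip(iu[keep], ju[keep])]

    # knockdown screens overlapping the planted truth
    cc_genes = [g for g in gene_ids if labels[g] == 1]
    non_cc = [g for g in gene_ids if labels[g] == 0]
    knockdown_sets: dict[str, set[str]] = {}
    for name in ("screen_A", "screen_B"):
        n_cc_hits = min(len(cc_genes), int(round(cfg.knockdown_overlap_rate * cfg.n_knockdown)))
        n_bg = min(len(non_cc), cfg.n_knockdown - n_cc_hits)
        hits = set(rng.choice(cc_genes, size=n_cc_hits, replace=False).tolist()) | set(
            rng.choice(non_cc, size=n_bg, replace=False).tolist()
        )
        knockdown_sets[name] = hits

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": [r.category for r in tss],
            "label": y,
            "peak_time": [peak_times.get(g, np.nan) for g in gene_ids],
            "expression": [expression[g] for g in gene_ids],
            "n_bound_tfs": bound.sum(axis=1).values,
            "n_planted_motifs": planted.sum(axis=1).values,
        }
    )

    return SimBundle(
        config=cfg,
        chrom_lengths=chrom_lengths,
        genome={c: ba.decode() for c, ba in genome.items()},
        tss=tss,
        tracks=tracks,
        matrices=matrices,
        labels=labels,
        peak_times=peak_times,
        expression=expression,
        informative_tfs=informative_tfs,
        informative_motifs=informative_motifs,
        binding=bound,
        planted_motifs=planted,
        ppi_edges=ppi_edges,
        knockdown_sets=knockdown_sets,
        truth=truth,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle to disk in the standard formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = out / "genome.fa"
    write_fasta(bundle.genome, paths["genome"])
    paths["tss"] = out / "tss.bed"
    write_tss_bed(bundle.tss, paths["tss"])
    for tf, track in bundle.tracks.items():
        p = out / f"track_{tf}.bedgraph"
        write_bedgraph(track, p)
        paths[f"track_{tf}"] = p
    paths["matrices"] = out / "motifs.transfac"
    write_transfac(bundle.matrices, paths["matrices"])
    paths["cutoffs"] = out / "cutoffs.tsv"
    write_cutoffs({m.motif_id: (m.cutoff_mss, m.cutoff_css) for m in bundle.matrices}, paths["cutoffs"])
    paths["truth"] = out / "truth.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["expression"] = out / "expression.tsv"
    pd.Series(bundle.expression, name="expression").rename_axis("gene_id").to_csv(
        paths["expression"], sep="\t"
    )
    paths["labels"] = out / "labels.tsv"
    pd.Series(bundle.labels, name="label").rename_axis("gene_id").to_csv(paths["labels"], sep="\t")
    paths["ppi"] = out / "ppi_edges.tsv"
    pd.DataFrame(bundle.ppi_edges, columns=["gene_a", "gene_b"]).to_csv(
        paths["ppi"], sep="\t", index=False
    )
    for name, hits in bundle.knockdown_sets.items():
        p = out / f"knockdown_{name}.tsv"
        pd.Series(sorted(hits), name="gene_id").to_csv(p, sep="\t", index=False)
        paths[f"knockdown_{name}"] = p
    return paths
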