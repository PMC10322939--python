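"""Synthetic genomes with planted TSS-interdependence structure.

The generator emulates the features of real data the pipeline consumes: a
small genome with non-overlapping genes on both strands, 1–6 TSSs per gene
at controllable spacings, and strand-specific base-resolution signal in
which every TSS contributes additively a transcript-body profile (optional
initiation pulse, plateau over the body, exponential decay past the 3'
end).  Two interaction effects can be planted with known ground truth:

* suppression — a TSS whose next TSS lies within ``suppression_range``
  has its initiation scaled by ``suppression_factor`` (s < 1 models
  transcriptional interference by a near downstream promoter);
* cooperativity — when two consecutive TSSs are within
  ``coop_max_distance``, the total signal in the window extending
  ``coop_extent`` downstream of the downstream TSS is scaled by
  ``cooperativity_factor``.  Scaling the window (initiation plus
  read-through) rather than the downstream TSS's own contribution makes
  the planted proximal-cooperativity ratio exactly ``q`` regardless of how
  much upstream read-through overlaps the window.

Genes carry independent log-normal expression levels; replicates share all
structure and differ only through per-gene log-normal noise.  Everything is
driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .annotation import GeneLandmarks
from .signal import GenomicSignal, StrandedSignal, write_bedgraph, write_chrom_sizes


@dataclass(frozen=True)
class SpacingBands:
    """Mixture of uniform inter-TSS distance bands (bp, inclusive)."""

    bands: tuple[tuple[int, int], ...] = ((60, 200), (200, 900), (1_000, 2_000))
    weights: tuple[float, ...] = (0.35, 0.4, 0.25)
    labels: tuple[str, ...] = ("proximal", "intermediate", "distal")

    def __post_init__(self):
        if len(self.bands) != len(self.weights) or len(self.bands) != len(self.labels):
            raise ValueError("bands, weights and labels must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("spacing weights must sum to 1")
        for lo, hi in self.bands:
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid spacing band ({lo}, {hi})")

    def sample(self, rng: np.random.Generator) -> int:
        k = rng.choice(len(self.bands), p=self.weights)
        lo, hi = self.bands[k]
        return int(rng.integers(lo, hi + 1))

    def classify(self, d: int) -> str:
        for (lo, hi), label in zip(self.bands, self.labels):
            if lo <= d <= hi:
                return label
        return "other"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of a synthetic genome.

    Defaults give a ~2 Mb genome with 300 genes carrying 1–6 TSSs — the
    full pipeline on it runs in seconds.  ``recovery`` builds the
    configuration used for planted-effect recovery experiments: two-TSS
    genes with spacing bands matched to the proximal / intermediate /
    distal region semantics and transcript bodies long enough to cover the
    distal reference regions.
    """

    n_genes: int = 300
    tss_counts: tuple[tuple[int, float], ...] = (
        (1, 0.20), (2, 0.30), (3, 0.20), (4, 0.15), (5, 0.10), (6, 0.05)
    )
    spacing: SpacingBands = SpacingBands()
    base_rate: float = 5.0
    expr_sigma: float = 0.75          # per-gene log-normal expression spread
    noise_sigma: float = 0.3          # per-gene per-replicate log-normal noise
    decay_length: int = 300           # bp, exponential decay past the 3' end
    tail_length: int = 2_000          # bp of transcript body past the last TSS
    pulse_width: int = 100            # bp of the initiation pulse
    pulse_height: float = 1.0         # pulse multiplier over the body plateau
    suppression_factor: float = 1.0   # s
    suppression_range: tuple[int, int] = (200, 900)
    cooperativity_factor: float = 1.0  # q
    coop_max_distance: int = 200
    coop_extent: int = 1_000
    strand_p_plus: float = 0.5
    intergenic_gap: int = 1_000
    n_chroms: int = 2
    genome_length: int | None = 2_000_000  # None: auto-size to fit the genes
    chrom_prefix: str = "chr"

    def __post_init__(self):
        if abs(sum(p for _, p in self.tss_counts) - 1.0) > 1e-9:
            raise ValueError("tss_counts probabilities must sum to 1")
        if self.suppression_factor <= 0 or self.cooperativity_factor <= 0:
            raise ValueError("planted factors must be > 0")
        for name in ("decay_length", "tail_length", "coop_extent", "intergenic_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def decay_truncation(self) -> int:
        return 6 * self.decay_length

    @classmethod
    def recovery(cls, s: float = 1.0, q: float = 1.0, n_genes: int = 300) -> "SynthConfig":
        return cls(
            n_genes=n_genes,
            tss_counts=((2, 1.0),),
            spacing=SpacingBands(
                bands=((60, 200), (200, 900), (10_300, 19_800)),
                weights=(1 / 3, 1 / 3, 1 / 3),
            ),
            decay_length=200,
            tail_length=21_000,
            pulse_height=1.0,
            suppression_factor=s,
            cooperativity_factor=q,
            intergenic_gap=2_000,
            genome_length=None,
        )


@dataclass
class SynthGene:
    gene_id: str
    chrom: str
    strand: str
    tss: tuple[int, ...]          # genomic coordinates, transcription order
    spacings: tuple[int, ...]     # oriented inter-TSS distances
    three_prime: int              # genomic coordinate of the transcript 3' end
    expr: float                   # per-gene expression multiplier
    tss_factors: tuple[float, ...]  # initiation factors after suppression
    coop_windows: tuple[int, ...]   # TSS ranks (1-based) whose downstream window is enhanced


@dataclass
class SynthAnnotation:
    genes: list[GeneLandmarks]
    structures: list[SynthGene]
    chrom_sizes: dict[str, int]
    truth: pd.DataFrame
    config: SynthConfig


TRUTH_COLUMNS = [
    "gene_id", "chrom", "strand", "pair_index", "z_U", "z_D", "distance",
    "distance_class", "suppressed", "enhanced",
]


def generate_annotation(config: SynthConfig, seed: int) -> SynthAnnotation:
    """Sample gene structures and place them without overlap on the genome."""
    rng = np.random.default_rng([int(seed), 101])
    counts = np.array([c for c, _ in config.tss_counts])
    probs = np.array([p for _, p in config.tss_counts])
    trunc = config.decay_truncation
    d_lo, d_hi = config.suppression_range

    drafts = []
    for i in range(config.n_genes):
        n_tss = int(rng.choice(counts, p=probs))
        spacings = tuple(config.spacing.sample(rng) for _ in range(n_tss - 1))
        strand = "+" if rng.random() < config.strand_p_plus else "-"
        expr = float(rng.lognormal(0.0, config.expr_sigma))
        span_tx = sum(spacings) + config.tail_length
        factors = []
        coop = []
        for j in range(n_tss):
            f = 1.0
            if j < n_tss - 1 and d_lo <= spacings[j] <= d_hi:
                f *= config.suppression_factor
            factors.append(f)
            if j >= 1 and spacings[j - 1] <= config.coop_max_distance:
                coop.append(j + 1)
        drafts.append((n_tss, spacings, strand, expr, span_tx, tuple(factors), tuple(coop)))

    # sequential placement; footprint = transcript + decay tail + gap
    footprints = [span + trunc + config.intergenic_gap for _, _, _, _, span, _, _ in drafts]
    if config.genome_length is not None:
        chrom_len = config.genome_length // config.n_chroms
        sizes = {f"{config.chrom_prefix}{k + 1}": chrom_len for k in range(config.n_chroms)}
    else:
        per = math.ceil(sum(footprints) / config.n_chroms) if drafts else 1_000
        sizes = None  # finalized after placement
        chrom_len = per + (max(footprints) if footprints else 0) + config.intergenic_gap

    cursors = {f"{config.chrom_prefix}{k + 1}": config.intergenic_gap for k in range(config.n_chroms)}
    structures: list[SynthGene] = []
    genes: list[GeneLandmarks] = []
    truth_rows = []
    chrom_names = list(cursors)
    ci = 0
    for i, (n_tss, spacings, strand, expr, span_tx, factors, coop) in enumerate(drafts):
        fp = footprints[i]
        placed = False
        for _ in range(config.n_chroms):
            chrom = chrom_names[ci % config.n_chroms]
            if cursors[chrom] + fp <= chrom_len:
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError(
                f"genome too small for {config.n_genes} genes "
                f"(failed at gene {i + 1}; increase genome_length or reduce genes)"
            )
        c = cursors[chrom]
        cursors[chrom] = c + fp
        ci += 1
        cum = np.concatenate(([0], np.cumsum(spacings))).astype(int)
        if strand == "+":
            tss = tuple(int(c + u) for u in cum)
            three_prime = int(c + span_tx)
        else:
            first = c + span_tx + trunc
            tss = tuple(int(first - u) for u in cum)
            three_prime = int(first - span_tx)
        gid = f"SYNG{i + 1:05d}"
        sg = SynthGene(gid, chrom, strand, tss, spacings, three_prime, expr, factors, coop)
        structures.append(sg)
        genes.append(GeneLandmarks(gid, chrom, strand, tss, activity=config.base_rate * expr))
        for k, d in enumerate(spacings, start=1):
            truth_rows.append(
                (gid, chrom, strand, k, tss[k - 1], tss[k], d, config.spacing.classify(d),
                 d_lo <= d <= d_hi and config.suppression_factor != 1.0,
                 d <= config.coop_max_distance and config.cooperativity_factor != 1.0)
            )

    if config.genome_length is None:
        sizes = {c: cursors[c] + config.intergenic_gap for c in chrom_names}
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SynthAnnotation(genes=genes, structures=structures, chrom_sizes=sizes,
                           truth=truth, config=config)


def _profile(length_body: int, config: SynthConfig) -> np.ndarray:
    """Per-TSS contribution at oriented offsets 0..length_body+trunc−1."""
    trunc = config.decay_truncation
    prof = np.ones(length_body + trunc)
    if config.pulse_width > 0:
        prof[: min(config.pulse_width, len(prof))] = config.pulse_height
    u = np.arange(1, trunc + 1)
    prof[length_body:] = np.exp(-u / config.decay_length)
    return prof


def generate_signal(
    ann: SynthAnnotation, seed: int, replicate: int = 1
) -> tuple[StrandedSignal, dict[str, float]]:
    """Build the replicate's strand-specific tracks and its gene abundances.

    Replicates share all planted structure; only the per-gene log-normal
    noise factor is redrawn.  Returns the signal and a TPM-like
    quantification (per-gene realized rate).
    """
    config = ann.config
    rng = np.random.default_rng([int(seed), 202, int(replicate)])
    arrays = {
        s: {c: np.zeros(n) for c, n in ann.chrom_sizes.items()} for s in ("+", "-")
    }
    quant: dict[str, float] = {}
    enhancements = []  # (strand, chrom, z_D genomic, extent)
    for sg in ann.structures:
        noise = float(rng.lognormal(0.0, config.noise_sigma))
        rate = config.base_rate * sg.expr * noise
        quant[sg.gene_id] = rate
        arr = arrays[sg.strand][sg.chrom]
        cum = np.concatenate(([0], np.cumsum(sg.spacings))).astype(int)
        span_tx = sum(sg.spacings) + config.tail_length
        for j, z in enumerate(sg.tss):
            body = span_tx - int(cum[j])
            prof = rate * sg.tss_factors[j] * _profile(body, config)
            if sg.strand == "+":
                end = min(z + len(prof), len(arr))
                arr[z:end] += prof[: end - z]
            else:
                start = max(z - len(prof) + 1, 0)
                arr[start : z + 1] += prof[: z + 1 - start][::-1]
        for rank in sg.coop_windows:
            enhancements.append((sg.strand, sg.chrom, sg.tss[rank - 1]))
    q = config.cooperativity_factor
    if q != 1.0:
        ext = config.coop_extent
        for strand, chrom, z in enhancements:
            arr = arrays[strand][chrom]
            if strand == "+":
                arr[z : min(z + ext, len(arr))] *= q
            else:
                arr[max(z - ext + 1, 0) : z + 1] *= q
    sig = StrandedSignal(GenomicSignal(arrays["+"]), GenomicSignal(arrays["-"]))
    return sig, quant


# -- file emission -----------------------------------------------------------

def write_gtf(ann: SynthAnnotation, path) -> None:
    """Gencode-dialect GTF with gene, transcript and exon records."""
    with open(path, "w") as fh:
        fh.write("##description: synthetic annotation (tssgrid generator)\n")
        for sg in ann.structures:
            lo = min(min(sg.tss), sg.three_prime) + 1  # 1-based inclusive
            hi = max(max(sg.tss), sg.three_prime) + 1
            attrs = (
                f'gene_id "{sg.gene_id}"; gene_type "protein_coding"; '
                f'gene_name "{sg.gene_id}";'
            )
            fh.write(f"{sg.chrom}\tsynth\tgene\t{lo}\t{hi}\t.\t{sg.strand}\t.\t{attrs}\n")
            for j, z in enumerate(sg.tss, start=1):
                if sg.strand == "+":
                    t_lo, t_hi = z + 1, sg.three_prime + 1
                else:
                    t_lo, t_hi = sg.three_prime + 1, z + 1
                t_attrs = attrs[:-1] + f' transcript_id "{sg.gene_id}.{j}";'
                fh.write(
                    f"{sg.chrom}\tsynth\ttranscript\t{t_lo}\t{t_hi}\t.\t{sg.strand}\t.\t{t_attrs}\n"
                )
                fh.write(
                    f"{sg.chrom}\tsynth\texon\t{t_lo}\t{t_hi}\t.\t{sg.strand}\t.\t{t_attrs}\n"
                )


def write_quantification(quant: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tTPM\n")
        for gid in sorted(quant):
            fh.write(f"{gid}\t{float(quant[gid])!r}\n")


def make_fixtures(config: SynthConfig, outdir, seed: int, replicates: int = 2) -> dict[str, Path]:
    """Emit a complete fixture set: GTF, chrom sizes, truth table, and per
    replicate strand-specific bedGraph tracks plus a gene quantification.

    Byte-identical across runs for a fixed config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = generate_annotation(config, seed)
    paths: dict[str, Path] = {
        "gtf": outdir / "annotation.gtf",
        "chrom_sizes": outdir / "chrom.sizes",
        "truth": outdir / "truth.tsv",
    }
    write_gtf(ann, paths["gtf"])
    write_chrom_sizes(ann.chrom_sizes, paths["chrom_sizes"])
    ann.truth.to_csv(paths["truth"], sep="\t", index=False)
    for rep in range(1, replicates + 1):
        sig, quant = generate_signal(ann, seed, replicate=rep)
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = outdir / f"rep{rep}.{tag}.bedGraph"
            write_bedgraph(sig.track(strand), p)
            paths[f"rep{rep}_{tag}"] = p
        qp = outdir / f"rep{rep}.quant.tsv"
        write_quantification(quant, qp)
        paths[f"rep{rep}_quant"] = qp
    return paths
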