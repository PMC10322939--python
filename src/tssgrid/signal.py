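"""Base-resolution signal tracks: loading, genome-wide normalization, and
strand-oriented access.

A :class:`GenomicSignal` holds one track as per-chromosome 1 bp arrays.
Bases with no data are 0.  Oriented access reads offsets in transcription
direction: offset +k means k bases downstream of the anchor, which is
``anchor+k`` on the plus strand and ``anchor-k`` on the minus strand.
Reads past chromosome ends return 0 (and are counted) so that distal
windows near contig edges never abort a sweep.

Stranded assays use a :class:`StrandedSignal` mapping each strand to its
track; unstranded assays reuse one track for both strands.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class SignalFormatError(ValueError):
    pass


def _resolve_chrom(name: str, available) -> str | None:
    """Reconcile the chr-prefix dialect between a requested name and a set."""
    if name in available:
        return name
    alt = name[3:] if name.startswith("chr") else "chr" + name
    return alt if alt in available else None


class GenomicSignal:
    """One signal track: ``chrom -> float array`` at 1 bp resolution."""

    def __init__(
        self,
        data: Mapping[str, np.ndarray],
        normalized: bool = False,
        genome_mean: float | None = None,
    ):
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        for c, v in self.data.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite signal values on {c}")
            if np.any(v < 0):
                raise ValueError(f"negative signal values on {c}")
        self.normalized = normalized
        self.genome_mean = genome_mean
        self.boundary_reads = 0

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[self._key(chrom)])

    def _key(self, chrom: str) -> str:
        key = _resolve_chrom(chrom, self.data)
        if key is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return key

    def total_bases(self) -> int:
        return sum(len(v) for v in self.data.values())

    def mean(self, mode: str = "all") -> float:
        """Genome-wide mean over all bases ("all") or nonzero bases ("covered")."""
        total = sum(float(v.sum()) for v in self.data.values())
        if mode == "all":
            n = self.total_bases()
        elif mode == "covered":
            n = sum(int(np.count_nonzero(v)) for v in self.data.values())
        else:
            raise ValueError(f"unknown mean mode {mode!r}")
        return total / n if n else 0.0

    # -- oriented access -----------------------------------------------------

    def oriented_value(self, chrom: str, strand: str, anchor: int, offset: int) -> float:
        """Signal at ``offset`` bases downstream of ``anchor`` on ``strand``."""
        arr = self.data[self._key(chrom)]
        pos = anchor + offset if strand == "+" else anchor - offset
        if pos < 0 or pos >= len(arr):
            self.boundary_reads += 1
            return 0.0
        return float(arr[pos])

    def oriented_slice(self, chrom: str, strand: str, anchor: int, lo: int, hi: int) -> np.ndarray:
        """Signal at oriented offsets ``lo..hi`` inclusive (length hi−lo+1).

        Offsets outside the chromosome are filled with 0 and counted in
        ``boundary_reads``.
        """
        if hi < lo:
            return np.empty(0)
        arr = self.data[self._key(chrom)]
        n = len(arr)
        out = np.zeros(hi - lo + 1)
        if strand == "+":
            a, b = anchor + lo, anchor + hi + 1  # genomic half-open
            ca, cb = max(a, 0), min(b, n)
            if ca < cb:
                out[ca - a : cb - a] = arr[ca:cb]
        elif strand == "-":
            a, b = anchor - hi, anchor - lo + 1
            ca, cb = max(a, 0), min(b, n)
            if ca < cb:
                out[b - cb : b - ca] = arr[ca:cb][::-1]
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        self.boundary_reads += (hi - lo + 1) - max(0, cb - ca)
        return out

    def mirrored(self) -> "GenomicSignal":
        """The genome read back-to-front (arrays reversed); used for symmetry checks."""
        sig = GenomicSignal({c: v[::-1].copy() for c, v in self.data.items()},
                            normalized=self.normalized, genome_mean=self.genome_mean)
        return sig

    def scaled(self, c: float) -> "GenomicSignal":
        if c <= 0:
            raise ValueError("scale factor must be > 0")
        return GenomicSignal({k: v * c for k, v in self.data.items()})


class StrandedSignal:
    """Strand-to-track mapping with the same oriented-access surface.

    For stranded assays (RNA-seq, RAMPAGE) pass separate plus/minus tracks;
    for unstranded assays (DNase-seq, ChIP-seq) pass the same track twice or
    use :meth:`unstranded`.
    """

    def __init__(self, plus: GenomicSignal, minus: GenomicSignal):
        self.tracks = {"+": plus, "-": minus}

    @classmethod
    def unstranded(cls, track: GenomicSignal) -> "StrandedSignal":
        return cls(track, track)

    def track(self, strand: str) -> GenomicSignal:
        return self.tracks[strand]

    def oriented_value(self, chrom, strand, anchor, offset):
        return self.tracks[strand].oriented_value(chrom, strand, anchor, offset)

    def oriented_slice(self, chrom, strand, anchor, lo, hi):
        return self.tracks[strand].oriented_slice(chrom, strand, anchor, lo, hi)

    def normalize(self, mode: str = "all") -> "StrandedSignal":
        plus = normalize_genomewide(self.tracks["+"], mode)
        if self.tracks["-"] is self.tracks["+"]:
            return StrandedSignal(plus, plus)
        return StrandedSignal(plus, normalize_genomewide(self.tracks["-"], mode))

    def mirrored(self) -> "StrandedSignal":
        return StrandedSignal(self.tracks["+"].mirrored(), self.tracks["-"].mirrored())


# -- loading -----------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def load_signal(
    path,
    chrom_whitelist: Sequence[str] | None = None,
    chrom_sizes: Mapping[str, int] | str | Path | None = None,
    negatives: str = "abs",
) -> GenomicSignal:
    """Load a bigWig or bedGraph track into per-base arrays.

    Bases without data are 0.  ``negatives`` controls values below zero
    (minus-strand coverage files often store negated values): ``"abs"``
    (default) takes absolute values, ``"zero"`` clips, ``"error"`` raises.
    ``chrom_sizes`` (mapping or two-column file) sets array lengths for
    bedGraph input; without it each array ends at the last covered base.
    """
    path = Path(path)
    if isinstance(chrom_sizes, (str, Path)):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if path.suffix.lower() in (".bw", ".bigwig"):
        data = _load_bigwig(path, chrom_whitelist)
    elif path.suffix.lower() in (".bedgraph", ".bg", ".bdg"):
        data = _load_bedgraph(path, chrom_whitelist, chrom_sizes)
    else:
        raise SignalFormatError(f"unknown signal format: {path.name} "
                                "(expected .bw/.bigwig or .bedGraph/.bg/.bdg)")
    if chrom_whitelist is not None and not data:
        raise SignalFormatError("no chromosomes in common between track and whitelist")
    for c, v in data.items():
        np.nan_to_num(v, copy=False)
        neg = v < 0
        if neg.any():
            if negatives == "abs":
                np.abs(v, out=v)
            elif negatives == "zero":
                v[neg] = 0.0
            else:
                raise SignalFormatError(f"negative values on {c}")
    return GenomicSignal(data)


def _load_bigwig(path, whitelist):
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        file_chroms = bw.chroms()
        wanted = list(file_chroms) if whitelist is None else [
            c for c in (_resolve_chrom(w, file_chroms) for w in whitelist) if c is not None
        ]
        data = {}
        for c in wanted:
            vals = bw.values(c, 0, file_chroms[c], numpy=True)
            data[c] = np.nan_to_num(np.asarray(vals, dtype=float))
        return data
    finally:
        bw.close()


def _load_bedgraph(path, whitelist, chrom_sizes):
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].isin(("track", "browser"))]
    data: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        if whitelist is not None and not any(_resolve_chrom(w, [chrom]) for w in whitelist):
            continue
        starts = sub["start"].to_numpy(int)
        ends = sub["end"].to_numpy(int)
        vals = sub["value"].to_numpy(float)
        if np.any(ends <= starts):
            raise SignalFormatError(f"bedGraph interval with end <= start on {chrom}")
        length = int(ends.max())
        if chrom_sizes is not None:
            key = _resolve_chrom(chrom, chrom_sizes)
            if key is not None:
                if chrom_sizes[key] < length:
                    raise SignalFormatError(f"{chrom}: intervals beyond declared size")
                length = chrom_sizes[key]
        arr = np.zeros(length)
        for s, e, v in zip(starts, ends, vals):
            arr[s:e] = v
        data[chrom] = arr
    if chrom_sizes is not None:
        for name, size in chrom_sizes.items():
            if name not in data and (whitelist is None or _chrom_in(name, whitelist)):
                data[name] = np.zeros(int(size))
    return data


def _chrom_in(name, whitelist):
    return _resolve_chrom(name, whitelist) is not None


def normalize_genomewide(signal: GenomicSignal, mode: str = "all") -> GenomicSignal:
    """Divide the track by its genome-wide average so the mean becomes 1.

    The mean is taken over every whitelisted base including zeros
    (``mode="all"``, the default) or over covered bases only
    (``mode="covered"``).  Idempotent: normalizing twice equals once.
    """
    mean = signal.mean(mode)
    if mean <= 0:
        raise ValueError("cannot normalize: genome-wide mean is zero")
    out = GenomicSignal(
        {c: v / mean for c, v in signal.data.items()},
        normalized=True,
        genome_mean=mean if not signal.normalized else signal.genome_mean,
    )
    return out


def write_bedgraph(signal: GenomicSignal, path) -> None:
    """Run-length encode a track to 4-column bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(signal.data):
            arr = signal.data[chrom]
            if len(arr) == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(arr)]))
            for s, e in zip(starts, ends):
                v = float(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")
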