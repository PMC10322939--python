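"""Gene annotation handling: TSS extraction, ordering, pairing, and activity strata.

A gene is reduced to its ordered list of transcription start sites (TSSs).
TSSs are enumerated in *transcription* order starting from the most upstream
one, so for a minus-strand gene the first TSS is the one with the largest
genomic coordinate.  Consecutive TSSs form oriented landmark pairs
(``z_U`` upstream, ``z_D`` downstream) which are the unit of the
two-dimensional alignment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line


class GtfParseError(ValueError):
    """A GTF line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"malformed GTF line {lineno}: {message}")


@dataclass(frozen=True)
class GeneLandmarks:
    """One gene's TSSs in transcription order, plus activity annotation.

    ``tss_positions`` are unique 0-based genomic coordinates, ascending for
    plus-strand genes and descending for minus-strand genes (most upstream
    first in both cases).
    """

    gene_id: str
    chrom: str
    strand: str
    tss_positions: tuple[int, ...]
    activity: float = 0.0
    stratum: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        pos = self.tss_positions
        if len(set(pos)) != len(pos):
            raise ValueError(f"{self.gene_id}: duplicate TSS positions")
        ordered = sorted(pos) if self.strand == "+" else sorted(pos, reverse=True)
        if list(pos) != ordered:
            raise ValueError(f"{self.gene_id}: TSSs not in transcription order")
        if self.activity < 0:
            raise ValueError(f"{self.gene_id}: activity must be >= 0")


@dataclass(frozen=True)
class LandmarkPair:
    """An oriented (upstream, downstream) TSS pair of one gene.

    ``z_U`` and ``z_D`` are genomic coordinates; ``distance`` is the oriented
    separation (always positive).  ``pair_index`` k means this is the
    (k-th, k+1-th) TSS pair in transcription order.
    """

    gene_id: str
    chrom: str
    strand: str
    z_U: int
    z_D: int
    pair_index: int

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError(
                f"{self.gene_id} pair {self.pair_index}: z_D must lie strictly "
                f"downstream of z_U in the oriented frame"
            )

    @property
    def distance(self) -> int:
        """Oriented distance z_D − z_U (> 0)."""
        return (self.z_D - self.z_U) if self.strand == "+" else (self.z_U - self.z_D)


@dataclass
class PairSet:
    """A collection of landmark pairs sharing a pair index and stratum."""

    pairs: list[LandmarkPair]
    pair_index: int
    stratum: str = "all"
    description: str = ""

    def __post_init__(self):
        for p in self.pairs:
            if p.pair_index != self.pair_index:
                raise ValueError("all pairs in a PairSet must share pair_index")

    def __iter__(self) -> Iterator[LandmarkPair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _chrom_ok(chrom: str, whitelist: Sequence[str] | None) -> bool:
    if whitelist is None:
        return True
    if chrom in whitelist:
        return True
    alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
    return alt in whitelist


def iter_gtf_features(source) -> Iterator[tuple[int, object]]:
    """Yield ``(lineno, gffutils.Feature)`` for each feature line of a GTF.

    ``source`` may be a path or an iterable of lines.  Comment, ``track`` and
    blank lines are skipped.  Parse failures raise :class:`GtfParseError`
    naming the offending line.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from iter_gtf_features(fh)
        return
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith(("track", "browser")):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted exception types
            raise GtfParseError(lineno, str(exc)) from exc
        if feat.start is None or feat.end is None:
            raise GtfParseError(lineno, "missing coordinates")
        yield lineno, feat


def extract_tss(
    source,
    gene_type_filter: str = "protein_coding",
    chrom_whitelist: Sequence[str] | None = None,
) -> list[GeneLandmarks]:
    """Extract per-gene ordered TSS lists from a Gencode-style GTF.

    The TSS of a transcript is its 5' end: the (1-based) ``start`` field for
    plus-strand records and the ``end`` field for minus-strand records, both
    converted to 0-based coordinates.  Duplicate TSS positions shared by
    several transcripts of a gene are collapsed.  Genes whose ``gene_type``
    does not match ``gene_type_filter`` are excluded (pass ``None`` to keep
    every gene).  Genes with a gene record but no transcripts are skipped
    with a warning.
    """
    tss: dict[str, set[int]] = {}
    meta: dict[str, tuple[str, str]] = {}
    seen_genes: set[str] = set()
    for lineno, feat in iter_gtf_features(source):
        attrs = feat.attributes
        gene_id = attrs.get("gene_id", [None])[0]
        if gene_id is None:
            continue
        if not _chrom_ok(feat.seqid, chrom_whitelist):
            continue
        gene_type = attrs.get("gene_type", attrs.get("gene_biotype", [None]))[0]
        if gene_type_filter is not None and gene_type is not None and gene_type != gene_type_filter:
            continue
        if feat.featuretype == "gene":
            seen_genes.add(gene_id)
            continue
        if feat.featuretype != "transcript":
            continue
        if feat.strand not in ("+", "-"):
            warnings.warn(f"line {lineno}: transcript of {gene_id} without strand, skipped")
            continue
        pos = (feat.start - 1) if feat.strand == "+" else (feat.end - 1)
        if gene_id in meta and meta[gene_id] != (feat.seqid, feat.strand):
            raise ValueError(f"{gene_id}: transcripts disagree on chromosome/strand")
        meta.setdefault(gene_id, (feat.seqid, feat.strand))
        tss.setdefault(gene_id, set()).add(pos)

    for gene_id in seen_genes - set(tss):
        warnings.warn(f"gene {gene_id} has no transcripts; skipped")

    out = []
    for gene_id, positions in tss.items():
        chrom, strand = meta[gene_id]
        ordered = sorted(positions, reverse=(strand == "-"))
        out.append(GeneLandmarks(gene_id, chrom, strand, tuple(ordered)))
    out.sort(key=lambda g: (g.chrom, min(g.tss_positions), g.gene_id))
    return out


def consecutive_pairs(genes: Iterable[GeneLandmarks], pair_index: int) -> list[LandmarkPair]:
    """Emit the (k-th, k+1-th) TSS pair of every gene with at least k+1 TSSs."""
    if pair_index < 1:
        raise ValueError(f"pair_index must be >= 1, got {pair_index}")
    pairs = []
    for g in genes:
        if len(g.tss_positions) >= pair_index + 1:
            pairs.append(
                LandmarkPair(
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    strand=g.strand,
                    z_U=g.tss_positions[pair_index - 1],
                    z_D=g.tss_positions[pair_index],
                    pair_index=pair_index,
                )
            )
    return pairs


# -- activity stratification -------------------------------------------------

DEFAULT_BAND_LABELS = {
    5: ("low", "medium-low", "medium", "medium-high", "high"),
    3: ("low", "medium", "high"),
}


@dataclass(frozen=True)
class StratificationScheme:
    """Zero floor plus equal-count quantile bands over expressed genes."""

    n_bands: int = 5
    zero_floor: float = 0.0
    labels: tuple[str, ...] | None = None

    def band_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            if len(self.labels) != self.n_bands:
                raise ValueError("labels length must equal n_bands")
            return self.labels
        if self.n_bands in DEFAULT_BAND_LABELS:
            return DEFAULT_BAND_LABELS[self.n_bands]
        if self.n_bands == 1:
            return ("expressed",)
        mids = tuple(f"band-{i}" for i in range(2, self.n_bands))
        return ("low",) + mids + ("high",)


def stratify_by_activity(
    genes: Sequence[GeneLandmarks],
    quantification: Mapping[str, float],
    scheme: StratificationScheme | None = None,
) -> list[GeneLandmarks]:
    """Assign each gene an activity value and a stratum label.

    Genes with abundance at or below the scheme's zero floor (or absent from
    ``quantification``) go to the ``"zero"`` stratum; the rest are split into
    ``n_bands`` equal-count bands of increasing abundance, the highest band
    labelled ``"high"`` under the default scheme.
    """
    if scheme is None:
        scheme = StratificationScheme()
    if len(quantification) == 0:
        raise ValueError("empty quantification")
    for gid, val in quantification.items():
        try:
            v = float(val)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric abundance for gene {gid!r}: {val!r}") from exc
        if not np.isfinite(v):
            raise ValueError(f"non-finite abundance for gene {gid!r}: {val!r}")

    def lookup(gene_id: str) -> float:
        if gene_id in quantification:
            return float(quantification[gene_id])
        return float(quantification.get(strip_gene_version(gene_id), 0.0))

    activities = {g.gene_id: lookup(g.gene_id) for g in genes}
    expressed = sorted(
        (g.gene_id for g in genes if activities[g.gene_id] > scheme.zero_floor),
        key=lambda gid: (activities[gid], gid),
    )
    labels = scheme.band_labels()
    strata = {gid: "zero" for g in genes for gid in [g.gene_id] if gid not in expressed}
    n = len(expressed)
    for rank, gid in enumerate(expressed):
        strata[gid] = labels[rank * scheme.n_bands // n]
    return [replace(g, activity=activities[g.gene_id], stratum=strata[g.gene_id]) for g in genes]


_VERSION_RE = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    return _VERSION_RE.sub("", gene_id)


def read_quantification(
    path, column: str = "TPM", id_column: str = "gene_id"
) -> dict[str, float]:
    """Read an ENCODE-style tab-separated gene quantification table.

    Returns ``gene_id -> abundance`` with version suffixes (``.N``) stripped
    from gene ids.  Duplicate ids after stripping are summed.
    """
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns or column not in df.columns:
        raise ValueError(f"quantification table must have columns {id_column!r} and {column!r}")
    out: dict[str, float] = {}
    for gid, val in zip(df[id_column], df[column]):
        try:
            v = float(val)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric abundance for gene {gid!r}: {val!r}") from exc
        key = strip_gene_version(str(gid))
        out[key] = out.get(key, 0.0) + v
    if not out:
        raise ValueError("empty quantification")
    return out


# -- interchange table and BED export ---------------------------------------

LANDMARK_COLUMNS = ["gene_id", "chrom", "strand", "tss_rank", "position", "activity", "stratum"]


def landmarks_to_frame(genes: Iterable[GeneLandmarks]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for rank, pos in enumerate(g.tss_positions, start=1):
            rows.append((g.gene_id, g.chrom, g.strand, rank, pos, g.activity, g.stratum))
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def write_landmark_table(genes: Iterable[GeneLandmarks], path) -> None:
    landmarks_to_frame(genes).to_csv(path, sep="\t", index=False)


def read_landmark_table(path) -> list[GeneLandmarks]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"stratum": str})
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("tss_rank")
        genes.append(
            GeneLandmarks(
                gene_id=str(gid),
                chrom=str(sub["chrom"].iloc[0]),
                strand=str(sub["strand"].iloc[0]),
                tss_positions=tuple(int(p) for p in sub["position"]),
                activity=float(sub["activity"].iloc[0]),
                stratum=str(sub["stratum"].iloc[0]),
            )
        )
    genes.sort(key=lambda g: (g.chrom, min(g.tss_positions), g.gene_id))
    return genes


def write_tss_bed(genes: Iterable[GeneLandmarks], path) -> None:
    """BED6 export of TSS positions (name = gene_id.rank)."""
    with open(path, "w") as fh:
        for g in genes:
            for rank, pos in enumerate(g.tss_positions, start=1):
                fh.write(f"{g.chrom}\t{pos}\t{pos + 1}\t{g.gene_id}.{rank}\t0\t{g.strand}\n")
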