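"""Genome map, sequence, quality and species-tree structures with I/O.

Coordinates are 1-based inclusive internally (the GFF3 convention); any
BED output is converted to 0-based half-open at the boundary.  Gene maps
are gene-level only: one feature per gene plus explicit assembly-gap
intervals sharing the same structure.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional
from urllib.parse import quote, unquote

import dendropy
from Bio import SeqIO

#: Chromosome-name patterns treated as "unplaced" sequence.
UNPLACED_PATTERNS = (re.compile(r"Un", re.IGNORECASE), re.compile(r"_random$"))

NUCLEOTIDES = set("ACGTUNRYSWKMBDHV")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


def is_unplaced(chrom: str, patterns=UNPLACED_PATTERNS) -> bool:
    return any(p.search(chrom) for p in patterns)


class GenomeFormatError(ValueError):
    """Malformed GFF3/FASTA/FASTQ/Newick input."""


@dataclass(frozen=True, order=True)
class GeneFeature:
    """One gene (or assembly gap) placement on a chromosome."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    symbol: str
    strand: str = "+"
    is_gap: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeFormatError(
                f"{self.symbol}: start {self.start} > end {self.end}"
            )
        if self.strand not in "+-.":
            raise GenomeFormatError(f"{self.symbol}: bad strand {self.strand!r}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open coordinates."""
        return self.chrom, self.start - 1, self.end


@dataclass
class GenomeMap:
    """Ordered gene placements per chromosome for one species."""

    species: str
    features: dict[str, list[GeneFeature]] = field(default_factory=dict)
    gaps: dict[str, list[GeneFeature]] = field(default_factory=dict)

    def add(self, feature: GeneFeature) -> None:
        store = self.gaps if feature.is_gap else self.features
        store.setdefault(feature.chrom, []).append(feature)

    def sort(self) -> None:
        for store in (self.features, self.gaps):
            for chrom in store:
                store[chrom].sort(key=lambda f: (f.start, f.end, f.symbol))

    def all_features(self) -> list[GeneFeature]:
        return [f for chrom in sorted(self.features) for f in self.features[chrom]]

    def find(self, symbol: str) -> GeneFeature:
        for chrom_feats in self.features.values():
            for f in chrom_feats:
                if f.symbol == symbol:
                    return f
        raise KeyError(f"locus {symbol!r} not in map for {self.species}")

    def __contains__(self, symbol: str) -> bool:
        try:
            self.find(symbol)
        except KeyError:
            return False
        return True

    def gaps_in(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        return [
            g for g in self.gaps.get(chrom, []) if g.overlaps(chrom, start, end)
        ]


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide or amino-acid sequence with optional Phred qualities."""

    id: str
    residues: str
    qualities: Optional[tuple[int, ...]] = None
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        letters = set(self.residues.upper()) - {"-"}
        valid = NUCLEOTIDES if self.alphabet == "nucleotide" else AMINO_ACIDS
        if self.alphabet not in ("nucleotide", "protein"):
            raise GenomeFormatError(f"{self.id}: bad alphabet {self.alphabet!r}")
        if not letters <= valid:
            raise GenomeFormatError(
                f"{self.id}: residues outside {self.alphabet} alphabet: "
                f"{sorted(letters - valid)}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise GenomeFormatError(
                f"{self.id}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


_ATTR_SYMBOL_KEYS = ("symbol", "Name", "gene_name", "ID")


def read_gene_map(path: str | Path, species: str) -> GenomeMap:
    """Read gene-level GFF3 into a GenomeMap.

    ``gene`` rows become features (symbol taken from the first of
    symbol/Name/gene_name/ID attributes); ``gap`` rows become gap
    intervals.  Other feature types are ignored.
    """
    gmap = GenomeMap(species=species)
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype not in ("gene", "gap"):
                continue
            attributes = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attributes[key.strip()] = unquote(value.strip())
            symbol = next(
                (attributes[k] for k in _ATTR_SYMBOL_KEYS if k in attributes), None
            )
            if ftype == "gene" and symbol is None:
                raise GenomeFormatError(
                    f"{path}:{lineno}: gene feature lacks a symbol attribute"
                )
            try:
                feature = GeneFeature(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    symbol=symbol or f"gap_{lineno}",
                    strand=strand if strand in "+-." else ".",
                    is_gap=(ftype == "gap"),
                )
            except (ValueError, GenomeFormatError) as exc:
                raise GenomeFormatError(f"{path}:{lineno}: {exc}") from exc
            gmap.add(feature)
    gmap.sort()
    return gmap


def write_gene_map(gmap: GenomeMap, path: str | Path) -> None:
    """Emit a GenomeMap as GFF3 (genes and gaps), preserving coordinates."""
    lines = ["##gff-version 3"]
    entries = []
    for store, ftype in ((gmap.features, "gene"), (gmap.gaps, "gap")):
        for chrom in store:
            for f in store[chrom]:
                attrs = f"ID={quote(f.symbol)};symbol={quote(f.symbol)}"
                entries.append(
                    (f.chrom, f.start, f.symbol,
                     f"{f.chrom}\tkcurate\t{ftype}\t{f.start}\t{f.end}\t.\t"
                     f"{f.strand}\t.\t{attrs}")
                )
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    lines.extend(e[3] for e in entries)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def neighborhood(
    gmap: GenomeMap, locus: str, k: int
) -> tuple[list[str], list[str], list[GeneFeature]]:
    """Flanking gene symbols around ``locus``, nearest first.

    Returns ``(upstream, downstream, gaps)`` where upstream/downstream
    hold up to ``k`` symbols each (no padding at chromosome ends) and
    ``gaps`` lists assembly-gap intervals inside the window spanned by
    the returned flanks.
    """
    target = gmap.find(locus)
    chrom_feats = gmap.features[target.chrom]
    idx = next(
        i for i, f in enumerate(chrom_feats)
        if f.symbol == locus and f.start == target.start
    )
    upstream_feats = chrom_feats[max(0, idx - k): idx]
    downstream_feats = chrom_feats[idx + 1: idx + 1 + k]
    upstream = [f.symbol for f in reversed(upstream_feats)]
    downstream = [f.symbol for f in downstream_feats]
    window_start = upstream_feats[0].start if upstream_feats else target.start
    window_end = downstream_feats[-1].end if downstream_feats else target.end
    gaps = gmap.gaps_in(target.chrom, window_start, window_end)
    return upstream, downstream, gaps


def read_sequences(path: str | Path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read FASTA or FASTQ (Sanger, offset 33) into SequenceRecords."""
    path = Path(path)
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    if name.endswith((".fq", ".fastq")):
        fmt = "fastq"
    elif name.endswith((".fa", ".fasta", ".faa", ".fna")):
        fmt = "fasta"
    else:
        raise GenomeFormatError(f"{path}: unrecognized sequence format")
    records = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            quals = None
            if fmt == "fastq":
                quals = tuple(rec.letter_annotations["phred_quality"])
            records.append(
                SequenceRecord(
                    id=rec.id, residues=str(rec.seq), qualities=quals,
                    alphabet=alphabet,
                )
            )
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write FASTA (no qualities) or FASTQ (qualities present) by suffix."""
    path = Path(path)
    fastq = path.name.endswith((".fq", ".fastq"))
    with open(path, "w", encoding="utf-8") as out:
        for rec in records:
            if fastq:
                if rec.qualities is None:
                    raise GenomeFormatError(f"{rec.id}: FASTQ needs qualities")
                qline = "".join(chr(q + 33) for q in rec.qualities)
                out.write(f"@{rec.id}\n{rec.residues}\n+\n{qline}\n")
            else:
                out.write(f">{rec.id}\n{rec.residues}\n")


def read_tree(path_or_text: str | Path) -> dendropy.Tree:
    """Read a Newick species tree (path or literal newick text)."""
    text = None
    candidate = Path(str(path_or_text))
    try:
        if candidate.is_file():
            text = candidate.read_text(encoding="utf-8")
    except OSError:
        pass
    if text is None:
        text = str(path_or_text)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise GenomeFormatError(f"malformed newick: {exc}") from exc
    tree.is_rooted = True
    return tree


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
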