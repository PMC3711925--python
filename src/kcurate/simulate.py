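"""Synthetic multi-species fixtures with known ground truth.

Generates gene orders evolved down a species tree with planted
duplications, losses, alleles, pseudogenes and indels, plus coding
sequences evolved under per-gene dN/dS (omega) with a proposal-acceptance
codon model, and per-base quality tracks.  All randomness flows from a
single seeded generator; events are applied in list order after a
pre-order tree traversal, so bundles are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .genome import GeneFeature, GenomeMap, SequenceRecord, read_tree, write_gene_map, write_sequences
from .homology import SIDE_CHAIN_GROUPS
from .selection import CODON_TABLE, SENSE_CODONS, STOP_CODONS
from .variants import DomainAnnotation, classify_substitution


def config_domain_annotations(config: "SimulationConfig") -> dict[str, DomainAnnotation]:
    """Config domain intervals as DomainAnnotation objects, keyed by gene."""
    return {
        gene: DomainAnnotation(protein=gene, intervals=tuple(sorted(ivals)))
        for gene, ivals in config.domains.items()
    }

DEFAULT_TREE = (
    "(fish,(frog,((lizard,(chicken,finch)),(platypus,(mouse,human)))));"
)

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _v in _CODONS_BY_AA.values():
    _v.sort()


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EventSpec:
    """One planted event.

    ``clade`` lists the species affected (a tree-consistent leaf set for
    duplication/loss; a single species for allele/pseudogene/indel).
    ``params`` are event-specific knobs (edit counts, indel position...).
    """

    type: str
    gene: str
    clade: tuple[str, ...]
    params: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    seed: int = 0
    tree_newick: str = DEFAULT_TREE
    n_genes: int = 20
    codon_count: int = 500
    kappa: float = 1.0
    branch_divergence: float = 0.1  # expected proposals per nucleotide site
    omega_default: float = 0.02
    omega: dict[str, float] = field(default_factory=dict)
    events: tuple[EventSpec, ...] = ()
    base_phred: int = 60
    domains: dict[str, tuple[tuple[int, int, str], ...]] = field(default_factory=dict)


def default_config(seed: int = 0) -> SimulationConfig:
    """The default bundle: 20 genes, 8 species, the documented event set."""
    birds = ("chicken", "finch")
    sauropsids = ("lizard", "chicken", "finch")
    mammals = ("platypus", "mouse", "human")
    events = (
        EventSpec("duplication", "G003", birds),
        EventSpec("duplication", "G007", sauropsids),
        EventSpec("duplication", "G013", mammals),
        EventSpec("loss", "G005", ("mouse", "human")),
        EventSpec("loss", "G016", birds),
        EventSpec("allele", "G002", ("finch",),
                  {"synonymous": 2, "conservative": 1, "non_conservative": 0}),
        EventSpec("allele", "G011", ("finch",),
                  {"synonymous": 1, "conservative": 0, "non_conservative": 1}),
        EventSpec("pseudogene", "G009", ("finch",)),
        EventSpec("indel", "G004", ("finch",),
                  {"kind": "deletion", "position": 50, "length": 2}),
        EventSpec("indel", "G014", ("chicken",),
                  {"kind": "insertion", "position": 100, "length": 3}),
    )
    return SimulationConfig(
        seed=seed,
        events=events,
        omega={"G006": 0.5, "G017": 0.8},
        domains={
            "G004": ((40, 70, "ion_transport"),),
            "G014": ((90, 120, "transmembrane"),),
        },
    )


# ---------------------------------------------------------------------------
# Codon-sequence evolution


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG followed by random sense codons (no stops anywhere)."""
    if n_codons < 2:
        raise SimulationError("need at least 2 codons")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


def evolve_codons(
    parent: str,
    divergence: float,
    kappa: float,
    omega: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a coding sequence under a proposal-acceptance codon model.

    Single-nucleotide proposals arrive as a Poisson process at
    ``divergence`` expected proposals per site, with transition bias
    ``kappa``.  Proposals creating stop codons are rejected; synonymous
    proposals are accepted at rate min(1, 1/omega) and nonsynonymous at
    min(1, omega), so the realized dN/dS matches omega.  The start codon
    is held fixed.
    """
    if omega < 0:
        raise SimulationError("omega must be >= 0")
    codons = [parent[i: i + 3] for i in range(0, len(parent), 3)]
    n_sites = len(parent)
    n_events = rng.poisson(divergence * n_sites)
    accept_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    accept_non = min(1.0, omega)
    for _ in range(n_events):
        site = int(rng.integers(0, n_sites))
        ci, pos = divmod(site, 3)
        if ci == 0:
            continue  # protect the start codon
        old = codons[ci]
        old_base = old[pos]
        # transition with probability kappa/(kappa+2), else a transversion
        if rng.random() < kappa / (kappa + 2.0):
            new_base = _TRANSITIONS[old_base]
        else:
            choices = [b for b in _BASES if b != old_base and b != _TRANSITIONS[old_base]]
            new_base = choices[int(rng.integers(0, 2))]
        new = old[:pos] + new_base + old[pos + 1:]
        if new in STOP_CODONS:
            continue
        if CODON_TABLE[new] == CODON_TABLE[old]:
            if rng.random() < accept_syn:
                codons[ci] = new
        else:
            if rng.random() < accept_non:
                codons[ci] = new
    return "".join(codons)


# ---------------------------------------------------------------------------
# Bundle generation


@dataclass
class Bundle:
    config: SimulationConfig
    tree_newick: str
    species: list[str]
    maps: dict[str, GenomeMap]
    sequences: dict[str, dict[str, SequenceRecord]]  # species -> symbol -> record
    ground_truth: dict


def _layout_map(species: str, order: dict[str, list[str]],
                sequences: dict[str, SequenceRecord],
                gaps: dict[str, list[tuple[int, int]]] | None = None) -> GenomeMap:
    """Assign coordinates from gene order with fixed 1 kb spacing."""
    gmap = GenomeMap(species=species)
    for chrom, symbols in order.items():
        cursor = 1
        for symbol in symbols:
            length = len(sequences[symbol]) if symbol in sequences else 900
            gmap.add(GeneFeature(chrom=chrom, start=cursor,
                                 end=cursor + length - 1, symbol=symbol))
            cursor += length + 1000
    for chrom, intervals in (gaps or {}).items():
        for i, (start, end) in enumerate(intervals):
            gmap.add(GeneFeature(chrom=chrom, start=start, end=end,
                                 symbol=f"gap_{chrom}_{i}", is_gap=True))
    gmap.sort()
    return gmap


def _clade_species(tree, clade: tuple[str, ...], all_species: list[str]) -> list[str]:
    unknown = set(clade) - set(all_species)
    if unknown:
        raise SimulationError(f"event names unknown species {sorted(unknown)}")
    return [sp for sp in all_species if sp in clade]


def _plant_allele_edits(
    seq: str, params: dict, rng: np.random.Generator
) -> tuple[str, list[dict]]:
    """Apply planted codon edits of requested classes; return edits list."""
    codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
    n_codons = len(codons)
    wanted = (
        [("synonymous", None)] * int(params.get("synonymous", 0))
        + [("conservative", None)] * int(params.get("conservative", 0))
        + [("non_conservative", None)] * int(params.get("non_conservative", 0))
    )
    used: set[int] = set()
    edits: list[dict] = []
    for klass, _ in wanted:
        for _attempt in range(1000):
            idx = int(rng.integers(1, n_codons))  # never the start codon
            if idx in used:
                continue
            old = codons[idx]
            aa = CODON_TABLE[old]
            if klass == "synonymous":
                options = [c for c in _CODONS_BY_AA[aa] if c != old]
                if not options:
                    continue
                new = options[int(rng.integers(0, len(options)))]
                new_aa = aa
            else:
                group = next((g for g in SIDE_CHAIN_GROUPS if aa in g), frozenset())
                if klass == "conservative":
                    aas = sorted(group - {aa})
                else:
                    aas = sorted(set(_CODONS_BY_AA) - group - {aa})
                if not aas:
                    continue
                new_aa = aas[int(rng.integers(0, len(aas)))]
                choices = _CODONS_BY_AA[new_aa]
                new = choices[int(rng.integers(0, len(choices)))]
                if classify_substitution(aa, new_aa) != klass:
                    continue
            codons[idx] = new
            used.add(idx)
            edits.append({
                "position": idx + 1, "ref_aa": aa, "alt_aa": new_aa,
                "codon_ref": old, "codon_alt": new, "klass": klass,
            })
            break
        else:
            raise SimulationError(f"could not plant a {klass} edit")
    edits.sort(key=lambda e: e["position"])
    return "".join(codons), edits


def simulate_genomes(config: SimulationConfig) -> Bundle:
    """Evolve an ancestral genome down the tree and apply planted events."""
    rng = np.random.default_rng(config.seed)
    tree = read_tree(config.tree_newick)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    genes = [f"G{i:03d}" for i in range(1, config.n_genes + 1)]
    half = (config.n_genes + 1) // 2
    base_order = {"chr1": genes[:half], "chr2": genes[half:]}
    omega = {g: config.omega.get(g, config.omega_default) for g in genes}

    # ancestral sequences, then pre-order descent along the tree
    ancestral = {g: random_coding_sequence(config.codon_count, rng) for g in genes}
    node_seqs: dict[int, dict[str, str]] = {}
    tip_seqs: dict[str, dict[str, str]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_seqs[id(node)] = dict(ancestral)
            continue
        parent_seqs = node_seqs[id(node.parent_node)]
        evolved = {
            g: evolve_codons(parent_seqs[g], config.branch_divergence,
                             config.kappa, omega[g], rng)
            for g in genes
        }
        node_seqs[id(node)] = evolved
        if node.is_leaf():
            tip_seqs[node.taxon.label] = evolved

    orders = {sp: {c: list(s) for c, s in base_order.items()} for sp in species}
    sequences: dict[str, dict[str, str]] = {
        sp: dict(tip_seqs[sp]) for sp in species
    }
    truth: dict = {
        "duplications": [], "losses": [], "alleles": [], "pseudogenes": [],
        "indels": [], "omega": omega,
    }
    lost: dict[str, set[str]] = {g: set() for g in genes}
    loc_counter = 9000

    def next_loc() -> str:
        nonlocal loc_counter
        loc_counter += 1
        return f"LOC{loc_counter}"

    for event in config.events:
        members = _clade_species(tree, event.clade, species)
        gene = event.gene
        if gene not in genes:
            raise SimulationError(f"event targets unknown gene {gene}")
        if event.type == "loss":
            for sp in members:
                for chrom in orders[sp]:
                    orders[sp][chrom] = [s for s in orders[sp][chrom] if s != gene]
                sequences[sp].pop(gene, None)
                lost[gene].add(sp)
            truth["losses"].append({"gene": gene, "clade": sorted(members)})
        elif event.type == "duplication":
            # one insertion point, shared across the clade -> conserved flanks
            parent_chrom = next(c for c, s in base_order.items() if gene in s)
            host = "chr2" if parent_chrom == "chr1" else "chr1"
            slot = int(rng.integers(1, len(base_order[host]) - 1))
            copies: dict[str, str] = {}
            for sp in members:
                if sp in lost[gene]:
                    raise SimulationError(
                        f"duplication of {gene} in {sp} below its loss"
                    )
                symbol = next_loc()
                seq = evolve_codons(sequences[sp][gene], 0.02, config.kappa,
                                    omega[gene], rng)
                sequences[sp][symbol] = seq
                orders[sp][host].insert(slot, symbol)
                copies[sp] = symbol
            truth["duplications"].append({
                "gene": gene, "species": copies, "host_chrom": host,
            })
        elif event.type == "allele":
            (sp,) = members
            if sp in lost[gene]:
                raise SimulationError(f"allele of {gene} in {sp} below its loss")
            symbol = next_loc()
            scaffold = f"chrUn_scaf{loc_counter}"
            seq, edits = _plant_allele_edits(sequences[sp][gene], event.params, rng)
            sequences[sp][symbol] = seq
            orders[sp][scaffold] = [symbol]
            truth["alleles"].append({
                "gene": gene, "species": sp, "symbol": symbol,
                "scaffold": scaffold, "edits": edits,
            })
        elif event.type == "pseudogene":
            (sp,) = members
            symbol = next_loc()
            parent_seq = sequences[sp][gene]
            keep = (int(len(parent_seq) // 3 * 0.6)) * 3
            seq = "GTG" + parent_seq[3:keep]  # start codon ablated + truncated
            sequences[sp][symbol] = seq
            parent_chrom = next(
                c for c, s in orders[sp].items() if gene in s
            )
            idx = orders[sp][parent_chrom].index(gene)
            orders[sp][parent_chrom].insert(idx + 1, symbol)
            truth["pseudogenes"].append({
                "gene": gene, "species": sp, "symbol": symbol,
            })
        elif event.type == "indel":
            (sp,) = members
            kind = event.params["kind"]
            pos = int(event.params["position"])  # 1-based residue
            length = int(event.params["length"])
            seq = sequences[sp][gene]
            codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
            if kind == "deletion":
                removed = codons[pos - 1: pos - 1 + length]
                residues = "".join(CODON_TABLE[c] for c in removed)
                del codons[pos - 1: pos - 1 + length]
            elif kind == "insertion":
                inserted = [
                    SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
                    for _ in range(length)
                ]
                residues = "".join(CODON_TABLE[c] for c in inserted)
                codons[pos - 1: pos - 1] = inserted
            else:
                raise SimulationError(f"bad indel kind {kind!r}")
            sequences[sp][gene] = "".join(codons)
            truth["indels"].append({
                "gene": gene, "species": sp, "kind": kind,
                "position": pos, "length": length, "residues": residues,
            })
        else:
            raise SimulationError(f"unknown event type {event.type!r}")

    seq_records: dict[str, dict[str, SequenceRecord]] = {}
    maps: dict[str, GenomeMap] = {}
    for sp in species:
        records = {
            symbol: SequenceRecord(
                id=symbol, residues=seq,
                qualities=tuple([config.base_phred] * len(seq)),
            )
            for symbol, seq in sequences[sp].items()
        }
        seq_records[sp] = records
        maps[sp] = _layout_map(sp, orders[sp], records)
    return Bundle(
        config=config,
        tree_newick=config.tree_newick,
        species=species,
        maps=maps,
        sequences=seq_records,
        ground_truth=truth,
    )


def emit_bundle(bundle: Bundle, out_dir: str | Path, force: bool = False) -> dict:
    """Write the bundle to disk; returns the manifest (also written)."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise SimulationError(f"{out} is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for sp in bundle.species:
        gff = out / f"{sp}.gff3"
        write_gene_map(bundle.maps[sp], gff)
        files.append(gff)
        records = [bundle.sequences[sp][s] for s in sorted(bundle.sequences[sp])]
        fasta = out / f"{sp}.cds.fasta"
        fastq = out / f"{sp}.cds.fastq"
        write_sequences(records, fasta)
        write_sequences(records, fastq)
        files.extend([fasta, fastq])
    tree_path = out / "tree.nwk"
    tree_path.write_text(bundle.tree_newick + "\n")
    files.append(tree_path)
    domains_path = out / "domains.tsv"
    lines = ["protein\tstart\tend\tlabel"]
    for protein in sorted(bundle.config.domains):
        for start, end, label in bundle.config.domains[protein]:
            lines.append(f"{protein}\t{start}\t{end}\t{label}")
    domains_path.write_text("\n".join(lines) + "\n")
    files.append(domains_path)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(bundle.ground_truth, indent=1, sort_keys=True))
    files.append(truth_path)
    config_dict = asdict(bundle.config)
    config_dict["events"] = [asdict(e) for e in bundle.config.events]
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": bundle.config.seed,
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
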