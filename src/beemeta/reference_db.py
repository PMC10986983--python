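"""Curated regional reference database for barcode assignment.

References are taxonomy-tagged barcode sequences trimmed to the region
internal to the amplification primers.  Two database modes mirror common
curation practice: an *inclusive* mode (lower length floor, duplicates
kept) used as the chimera reference, and a *curated* mode (higher length
floor, dereplicated within each taxon) used for assignment.

FASTA headers carry the accession plus a semicolon-delimited rank-tagged
lineage (``tax=p:...,c:...,o:...,f:...,g:...,s:...``), the layout used by
kmer classifiers such as SINTAX.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import Lineage, TaxonomyTree

_RANK_TAGS = {"p": "phylum", "c": "class", "o": "order",
              "f": "family", "g": "genus", "s": "species"}
_TAG_FOR_RANK = {v: k for k, v in _RANK_TAGS.items()}

_AMBIGUOUS = set("RYSWKMBDHVN")


@dataclass(frozen=True)
class RefSeq:
    """One taxonomy-tagged reference barcode sequence."""

    accession: str
    taxid: int
    lineage: Lineage
    sequence: str
    source: str = "synthetic"  # genbank-like | bold-like | synthetic

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ambiguous_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        n_amb = sum(1 for ch in self.sequence.upper() if ch in _AMBIGUOUS)
        return n_amb / len(self.sequence)


@dataclass
class CuratedDB:
    """A set of reference sequences plus its curation mode."""

    sequences: list[RefSeq] = field(default_factory=list)
    mode: str = "curated"  # inclusive | curated
    min_length: int = 400  # 250 for inclusive mode
    dereplicated: bool = False

    def __len__(self) -> int:
        return len(self.sequences)

    def taxids(self) -> set[int]:
        return {r.taxid for r in self.sequences}


def filter_candidates(
    seqs: list[RefSeq],
    checklist: set[int],
    tree: TaxonomyTree,
    min_length: int = 400,
    max_ambig: float = 0.04,
) -> list[RefSeq]:
    """Retain candidates passing length, ambiguity, and checklist filters.

    Checklist membership is tested at species level with a genus fallback: a
    candidate survives if its taxid (or species ancestor) is on the
    checklist, or — for sequences labelled only to genus — if its genus
    matches the genus of any checklist species.  The checklist mirrors a
    regional species list resolved to taxids.
    """
    if not checklist:
        raise ValueError("checklist must be nonempty")
    checklist_genera = set()
    for taxid in checklist:
        genus = tree.ancestor_at_rank(taxid, "genus")
        if genus is not None:
            checklist_genera.add(genus.taxid)

    kept = []
    for seq in seqs:
        if seq.length < min_length:
            continue
        if seq.ambiguous_fraction > max_ambig:
            continue
        taxid = tree.effective_taxid(seq.taxid)
        if taxid in checklist:
            kept.append(seq)
            continue
        genus = tree.ancestor_at_rank(taxid, "genus")
        if genus is not None and genus.taxid in checklist_genera:
            kept.append(seq)
    return kept


def dereplicate_within_taxon(seqs: list[RefSeq]) -> list[RefSeq]:
    """Collapse exact full-length duplicates sharing a taxid to one record.

    Near-duplicates are kept; dereplication never crosses taxon boundaries.
    The first record (input order) of each duplicate group survives.
    """
    seen: set[tuple[int, str]] = set()
    kept = []
    for seq in seqs:
        key = (seq.taxid, seq.sequence.upper())
        if key in seen:
            continue
        seen.add(key)
        kept.append(seq)
    return kept


def build_db(
    candidates: list[RefSeq],
    checklist: set[int],
    tree: TaxonomyTree,
    mode: str = "curated",
    max_ambig: float = 0.04,
) -> CuratedDB:
    """Filter (and in curated mode dereplicate) candidates into a database."""
    if mode not in ("inclusive", "curated"):
        raise ValueError(f"unknown mode {mode!r}")
    min_length = 250 if mode == "inclusive" else 400
    kept = filter_candidates(candidates, checklist, tree,
                             min_length=min_length, max_ambig=max_ambig)
    dereplicated = False
    if mode == "curated":
        kept = dereplicate_within_taxon(kept)
        dereplicated = True
    return CuratedDB(kept, mode=mode, min_length=min_length, dereplicated=dereplicated)


def _lineage_to_tax_field(lineage: Lineage) -> str:
    return ",".join(f"{_TAG_FOR_RANK[rank]}:{name.replace(' ', '_')}"
                    for rank, taxid, name in lineage)


def write_db(db: CuratedDB, path: str | Path) -> None:
    """Write FASTA with ``accession taxid=N;tax=p:...,g:...,s:...;`` headers."""
    records = []
    for ref in db.sequences:
        desc = f"taxid={ref.taxid};tax={_lineage_to_tax_field(ref.lineage)};src={ref.source}"
        records.append(SeqRecord(Seq(ref.sequence), id=ref.accession, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_db(path: str | Path, tree: TaxonomyTree,
            mode: str = "curated") -> CuratedDB:
    """Read a rank-tagged FASTA back into a CuratedDB.

    A header may truncate its lineage from the specific end (e.g. stop at
    genus); an unknown rank tag or a missing taxid field is an error.
    """
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            part.split("=", 1)
            for part in rec.description.split(None, 1)[-1].rstrip(";").split(";")
            if "=" in part
        )
        if "taxid" not in fields:
            raise ValueError(f"malformed header for {rec.id}: no taxid field")
        taxid = int(fields["taxid"])
        for tag_pair in fields.get("tax", "").split(","):
            if tag_pair and tag_pair.split(":", 1)[0] not in _RANK_TAGS:
                raise ValueError(
                    f"unknown rank tag {tag_pair.split(':', 1)[0]!r} in header for {rec.id}")
        if taxid not in tree:
            raise ValueError(f"unresolvable lineage: taxid {taxid} not in taxonomy")
        refs.append(RefSeq(
            accession=rec.id,
            taxid=taxid,
            lineage=tree.lineage(taxid),
            sequence=str(rec.seq).upper(),
            source=fields.get("src", "synthetic"),
        ))
    min_length = 250 if mode == "inclusive" else 400
    return CuratedDB(refs, mode=mode, min_length=min_length,
                     dereplicated=(mode == "curated"))
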