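"""Pairwise alignment helpers shared by clustering and taxonomic scoring.

All identity and score computations run on edlib alignments.  Two metrics
are used throughout:

* ``matched bases`` — the count of identical aligned columns, the scoring
  metric for reference matching (a length-scaled similarity, like a BLAST
  score but self-contained).
* ``identity`` — matched columns divided by alignment columns, the
  edit-distance style identity used for clustering and demotion thresholds.

Columns where either sequence holds an N are excluded from both metrics, so
scaffold linker runs never contribute to a score or an identity.
"""

from __future__ import annotations

import re

import edlib

LINKER_RE = re.compile(r"N{5,}")

#: IUPAC code -> set of plain bases it stands for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_match(a: str, b: str) -> bool:
    """True when two IUPAC codes are compatible (share at least one base)."""
    sa = IUPAC.get(a.upper())
    sb = IUPAC.get(b.upper())
    if sa is None or sb is None:
        return False
    return not set(sa).isdisjoint(sb)


def split_on_linker(seq: str) -> list[str]:
    """Split a sequence on internal N-runs (scaffold linkers); drops the Ns."""
    parts = [p for p in LINKER_RE.split(seq) if p]
    return parts if parts else [seq]


def _walk_cigar(cigar: str, query: str, target: str, tstart: int) -> tuple[int, int]:
    """(matches, columns) over an extended cigar, skipping N columns."""
    qi, ti = 0, tstart
    matches = columns = 0
    for length, op in _CIGAR_RE.findall(cigar):
        length = int(length)
        if op in ("=", "X", "M"):
            qs = query[qi:qi + length]
            ts = target[ti:ti + length]
            qi += length
            ti += length
            if "N" not in qs and "N" not in ts:
                columns += length
                if op == "=":
                    matches += length
                else:
                    matches += sum(1 for a, b in zip(qs, ts) if a == b) if op == "M" else 0
            else:
                for a, b in zip(qs, ts):
                    if a == "N" or b == "N":
                        continue
                    columns += 1
                    if a == b:
                        matches += 1
        elif op == "I":  # insertion relative to target: consumes query
            qs = query[qi:qi + length]
            qi += length
            columns += length - qs.count("N")
        elif op == "D":
            ts = target[ti:ti + length]
            ti += length
            columns += length - ts.count("N")
    return matches, columns


def align_stats(query: str, target: str, mode: str = "NW") -> tuple[int, int]:
    """Align and return (matched_bases, alignment_columns), N columns excluded.

    ``mode`` follows edlib: NW is global, HW is semi-global with free end
    gaps on the target, so target bases outside the aligned span never
    penalize the query.
    """
    query = query.upper()
    target = target.upper()
    if not query or not target:
        return 0, max(len(query.replace("N", "")), len(target.replace("N", "")))
    res = edlib.align(query, target, mode=mode, task="path")
    tstart = res["locations"][0][0] if mode == "HW" else 0
    if tstart is None:
        tstart = 0
    return _walk_cigar(res["cigar"], query, target, tstart)


def global_identity(a: str, b: str) -> float:
    """Global (edit-distance style) identity: matches / alignment columns."""
    matches, columns = align_stats(a, b, mode="NW")
    return matches / columns if columns else 1.0


def segment_identity(a: str, b: str) -> float:
    """Identity between two templates, linker runs excluded.

    Scaffolded templates (fwd + N-linker + rev) are compared segment-wise
    when both sides split into the same number of segments; otherwise the
    sequences are aligned whole (N columns are skipped either way).
    """
    parts_a = split_on_linker(a)
    parts_b = split_on_linker(b)
    if len(parts_a) == len(parts_b) and len(parts_a) > 1:
        matches = columns = 0
        for pa, pb in zip(parts_a, parts_b):
            m, c = align_stats(pa, pb, mode="NW")
            matches += m
            columns += c
        return matches / columns if columns else 1.0
    return global_identity(a, b)


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Plain global edit distance; -1 when above the cutoff ``k``."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
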