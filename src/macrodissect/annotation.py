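"""Subunit annotation: dissecting chains into the eight subunit types.

Every polymer chain region is assigned to exactly one subunit type:

* protein chains — SCOP-family *domains* (from curated classifications or
  precomputed HMM-based family predictions supplied in the same format),
  *interdomain linkers* between two domains, *N-/C-terminal* regions outside
  the first/last domain, *peptides* (undomained chains shorter than 20
  residues) and *undefined chains* (undomained chains of 20+ residues);
* nucleic chains — each RNA chain is one subunit; a DNA chain is a subunit
  when at least one of its nucleotides is base-paired with a nucleotide of a
  different DNA chain.  Chains mixing DNA and RNA bases (hybrids) are
  reported and excluded.

All interval arithmetic runs on gap-free 0-based sequence indices; author
numbering is only used to resolve domain-assignment boundaries onto the
deposited structure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .structure_io import ChainModel, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "DomainAssignment",
    "SubunitSpan",
    "AnnotationParams",
    "PROTEIN_KINDS",
    "NUCLEIC_KINDS",
    "KIND_CODE",
    "KIND_ORDER",
    "read_scop_cla",
    "map_domains",
    "resolve_domains",
    "annotate_unstructured",
    "classify_undomained_chain",
    "identify_dna_subunits",
    "identify_rna_subunits",
    "annotate_structure",
]

PROTEIN_KINDS = frozenset(
    {"domain", "linker", "c_terminal", "n_terminal", "peptide",
     "undefined_chain"})
NUCLEIC_KINDS = frozenset({"dna", "rna"})

#: short codes used in interaction-type labels, in canonical order
KIND_CODE = {
    "domain": "D",
    "c_terminal": "C",
    "n_terminal": "N",
    "linker": "L",
    "undefined_chain": "U",
    "peptide": "P",
    "dna": "DNA",
    "rna": "RNA",
}
KIND_ORDER = ["domain", "c_terminal", "n_terminal", "linker",
              "undefined_chain", "peptide", "dna", "rna"]


@dataclass(frozen=True)
class DomainAssignment:
    """One segment of one domain-region assignment.

    Multi-segment (discontinuous) domains produce several assignments that
    share a ``domain_id``.  ``start``/``end`` are author residue identifiers
    (number + optional insertion code) or ``None`` for a whole-chain region.
    """

    pdb_id: str
    chain_id: str
    start: Optional[str]
    end: Optional[str]
    scop_family_id: str
    sunid: str = ""
    source: str = "scop_curated"  # or superfamily_predicted
    domain_id: str = ""

    def __post_init__(self):
        if not self.scop_family_id:
            raise ValueError("empty SCOP family id")


@dataclass(frozen=True)
class SubunitSpan:
    """A typed region of one chain, possibly discontinuous.

    ``segments`` are inclusive ``(start_index, end_index)`` intervals in
    0-based sequence coordinates, ordered and non-overlapping.  Regular
    subunits have one segment; a discontinuous domain keeps one span with
    several segments so that downstream interface counting pools them as one
    subunit.  ``label`` is the chain letter plus the 1-based ordinal of the
    span within its chain.
    """

    subunit_kind: str
    chain_id: str
    segments: tuple[tuple[int, int], ...]
    label: str = ""
    annotation: Optional[DomainAssignment] = None
    flags: frozenset = frozenset()

    def __post_init__(self):
        if not self.segments:
            raise ValueError("span needs at least one segment")
        for s, e in self.segments:
            if s > e:
                raise ValueError(f"inverted segment ({s}, {e})")

    @property
    def start_index(self) -> int:
        return self.segments[0][0]

    @property
    def end_index(self) -> int:
        return self.segments[-1][1]

    def indices(self) -> Iterator[int]:
        for s, e in self.segments:
            yield from range(s, e + 1)

    def n_units(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)

    @property
    def kind_code(self) -> str:
        return KIND_CODE[self.subunit_kind]


@dataclass(frozen=True)
class AnnotationParams:
    """Tunables of the annotation stage.

    ``peptide_max_len`` is the exclusive upper bound on the resolved length
    of an undomained chain classified as a peptide (default 20 residues,
    following the compendium definition of a peptide-length chain).
    """

    peptide_max_len: int = 20

    def __post_init__(self):
        if self.peptide_max_len < 1:
            raise ValueError("peptide_max_len must be >= 1")


# ---------------------------------------------------------------------------
# SCOP parseable-file input

_RANGE_RE = re.compile(r"^(-?\d+[A-Za-z]?)-(-?\d+[A-Za-z]?)$")


def _parse_region(region: str) -> list[tuple[str, Optional[str], Optional[str]]]:
    """Parse a dir.cla region field like ``A:``, ``A:2-77``, ``-`` or the
    multi-segment ``A:1-40,A:61-100`` into (chain, start, end) triples."""
    segments = []
    for part in region.split(","):
        part = part.strip()
        if part == "-":
            segments.append(("", None, None))
            continue
        if ":" not in part:
            raise ValueError(f"bad region {part!r}")
        chain, _, rng = part.partition(":")
        rng = rng.strip()
        if not rng:
            segments.append((chain, None, None))
            continue
        m = _RANGE_RE.match(rng)
        if not m:
            raise ValueError(f"bad range {rng!r}")
        segments.append((chain, m.group(1), m.group(2)))
    return segments


def read_scop_cla(path, source: str = "scop_curated") -> list[DomainAssignment]:
    """Read domain assignments from a ``dir.cla``-dialect file.

    Expected tab-separated columns: domain sid, PDB id, chain:range region,
    SCOP sccs, sunid (further columns ignored).  Comment lines starting with
    ``#`` are skipped; malformed rows are skipped with a warning.  An
    optional trailing column equal to ``superfamily`` marks a row as a
    precomputed prediction rather than a curated assignment.
    """
    assignments: list[DomainAssignment] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = re.split(r"\t|\s+", line.strip())
        if len(fields) < 4:
            logger.warning("dir.cla line %d: too few fields; skipped", lineno)
            continue
        sid, pdb_id, region = fields[0], fields[1], fields[2]
        sccs = fields[3]
        sunid = fields[4] if len(fields) > 4 else ""
        row_source = source
        if fields[-1].lower() in ("superfamily", "superfamily_predicted"):
            row_source = "superfamily_predicted"
        try:
            segments = _parse_region(region)
        except ValueError as exc:
            logger.warning("dir.cla line %d: %s; skipped", lineno, exc)
            continue
        domain_id = sid or f"{pdb_id}:{region}:{sccs}"
        for chain, start, end in segments:
            try:
                assignments.append(DomainAssignment(
                    pdb_id=pdb_id.lower(), chain_id=chain, start=start,
                    end=end, scop_family_id=sccs, sunid=sunid,
                    source=row_source, domain_id=domain_id))
            except ValueError as exc:
                logger.warning("dir.cla line %d: %s; skipped", lineno, exc)
    return assignments


# ---------------------------------------------------------------------------
# domain mapping

def _auth_index(chain: ChainModel) -> dict[str, int]:
    return {u.auth_seq_id: u.seq_index for u in chain.units}


def resolve_domains(chain: ChainModel,
                    assignments: Iterable[DomainAssignment]
                    ) -> tuple[list[SubunitSpan], list[str]]:
    """Resolve domain assignments onto a chain; return (spans, rejects).

    Assignments are grouped by domain identity; a domain is rejected as a
    whole (and listed in the report) if any segment boundary residue is
    absent from the deposited structure.  Overlaps between resolved domains
    are settled deterministically: curated assignments beat predictions,
    longer domains beat shorter, remaining ties go to the smaller start
    index.
    """
    index = _auth_index(chain)
    n = len(chain.units)
    groups: dict[str, list[DomainAssignment]] = {}
    for a in assignments:
        if a.chain_id and a.chain_id != chain.chain_id:
            continue
        if not a.chain_id and a.start is None and len(index) == 0:
            continue
        groups.setdefault(a.domain_id or id(a), []).append(a)

    resolved: list[tuple[DomainAssignment, tuple[tuple[int, int], ...]]] = []
    rejects: list[str] = []
    for domain_id, segs in groups.items():
        intervals = []
        ok = True
        for a in segs:
            if a.start is None:
                intervals.append((0, n - 1))
                continue
            s = index.get(a.start)
            e = index.get(a.end)
            if s is None or e is None or s > e:
                rejects.append(
                    f"domain {domain_id}: boundary {a.start}-{a.end} not "
                    f"locatable on chain {chain.chain_id}")
                ok = False
                break
            intervals.append((s, e))
        if ok:
            intervals.sort()
            resolved.append((segs[0], tuple(intervals)))

    # deterministic overlap resolution
    def priority(item):
        a, intervals = item
        length = sum(e - s + 1 for s, e in intervals)
        curated = 0 if a.source == "scop_curated" else 1
        return (curated, -length, intervals[0][0])

    accepted: list[SubunitSpan] = []
    taken = np.zeros(n, dtype=bool)
    for a, intervals in sorted(resolved, key=priority):
        cells = [i for s, e in intervals for i in range(s, e + 1)]
        if any(taken[i] for i in cells):
            rejects.append(
                f"domain {a.domain_id}: overlaps a higher-priority domain "
                f"on chain {chain.chain_id}")
            continue
        for i in cells:
            taken[i] = True
        accepted.append(SubunitSpan(
            subunit_kind="domain", chain_id=chain.chain_id,
            segments=intervals, annotation=a))
    accepted.sort(key=lambda s: s.start_index)
    return accepted, rejects


def map_domains(chain: ChainModel,
                assignments: Iterable[DomainAssignment]) -> list[SubunitSpan]:
    """Domain spans for one protein chain (rejects are logged)."""
    spans, rejects = resolve_domains(chain, assignments)
    for r in rejects:
        logger.warning("%s", r)
    return spans


def annotate_unstructured(chain: ChainModel,
                          domain_spans: Sequence[SubunitSpan]
                          ) -> list[SubunitSpan]:
    """Classify the unannotated intervals of a domain-bearing chain.

    Each maximal uncovered interval becomes one span: a linker when domains
    flank it on both sides, an N-terminal region when the only domains lie
    C-wards of it, and a C-terminal region when they lie N-wards.  The
    returned spans plus the domain spans tile the chain exactly.
    """
    n = len(chain.units)
    covered = np.zeros(n, dtype=bool)
    for span in domain_spans:
        for i in span.indices():
            if covered[i]:
                raise ValueError(
                    f"overlapping domain spans on chain {chain.chain_id}")
            covered[i] = True
    if not covered.any():
        raise ValueError("annotate_unstructured needs >=1 domain span")
    spans: list[SubunitSpan] = []
    i = 0
    while i < n:
        if covered[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not covered[j + 1]:
            j += 1
        left = covered[:i].any()
        right = covered[j + 1:].any()
        if left and right:
            kind = "linker"
        elif right:
            kind = "n_terminal"
        else:
            kind = "c_terminal"
        spans.append(SubunitSpan(subunit_kind=kind, chain_id=chain.chain_id,
                                 segments=((i, j),)))
        i = j + 1
    return spans


def classify_undomained_chain(chain: ChainModel,
                              params: AnnotationParams = AnnotationParams()
                              ) -> SubunitSpan:
    """Whole-chain span for a protein chain without any located domain:
    peptide when shorter than ``peptide_max_len`` resolved residues,
    undefined chain otherwise."""
    n = len(chain.units)
    kind = "peptide" if n < params.peptide_max_len else "undefined_chain"
    return SubunitSpan(subunit_kind=kind, chain_id=chain.chain_id,
                       segments=((0, n - 1),))


# ---------------------------------------------------------------------------
# nucleic subunits

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T", "U"}
_WC = {frozenset({"A", "T"}), frozenset({"G", "C"}), frozenset({"A", "U"})}


def _base_letter(comp_id: str) -> str:
    comp = comp_id.strip().upper()
    if len(comp) == 2 and comp.startswith("D"):
        return comp[1]
    return comp[-1] if comp else ""


def _geometric_dna_pairs(structure: StructureModel,
                         cutoff: float = 3.5) -> set[frozenset]:
    """Fallback inter-chain pairing test for inputs without base-pair
    records: two DNA chains count as paired when some Watson-Crick-compatible
    nucleotide pair has its purine N1 within ``cutoff`` of the pyrimidine
    N3."""
    dna_chains = [c for c in structure.chains if c.polymer_kind == "dna"]
    paired: set[frozenset] = set()
    for i, ca in enumerate(dna_chains):
        for cb in dna_chains[i + 1:]:
            if _chains_wc_paired(ca, cb, cutoff):
                paired.add(frozenset({ca.chain_id, cb.chain_id}))
    return paired


def _chains_wc_paired(ca: ChainModel, cb: ChainModel, cutoff: float) -> bool:
    for ua in ca.units:
        la = _base_letter(ua.comp_id)
        for ub in cb.units:
            lb = _base_letter(ub.comp_id)
            if frozenset({la, lb}) not in _WC:
                continue
            name_a = "N1" if la in _PURINES else "N3"
            name_b = "N1" if lb in _PURINES else "N3"
            pa = [a for a in ua.atoms if a.atom_name == name_a]
            pb = [b for b in ub.atoms if b.atom_name == name_b]
            for a in pa:
                for b in pb:
                    d = np.linalg.norm(np.subtract(a.coords, b.coords))
                    if d <= cutoff + 1e-9:
                        return True
    return False


def identify_dna_subunits(structure: StructureModel) -> list[SubunitSpan]:
    """Whole-chain DNA subunits.

    A DNA chain qualifies when at least one of its nucleotides is base-paired
    with a nucleotide of a *different* DNA chain, judged from the structure's
    base-pair records (or, when those are absent, a geometric Watson-Crick
    test).  Chains without such a partner are still returned but carry an
    ``unpaired`` flag; network assembly excludes them by default.
    """
    dna_chains = [c for c in structure.chains if c.polymer_kind == "dna"]
    if not dna_chains:
        return []
    dna_ids = {c.chain_id for c in dna_chains}
    paired: set[str] = set()
    if structure.base_pairs:
        for rec in structure.base_pairs:
            if (rec.chain_a != rec.chain_b and rec.chain_a in dna_ids
                    and rec.chain_b in dna_ids):
                paired.add(rec.chain_a)
                paired.add(rec.chain_b)
    else:
        for pair in _geometric_dna_pairs(structure):
            paired.update(pair)
    spans = []
    for chain in dna_chains:
        flags = frozenset() if chain.chain_id in paired \
            else frozenset({"unpaired"})
        spans.append(SubunitSpan(
            subunit_kind="dna", chain_id=chain.chain_id,
            segments=((0, len(chain.units) - 1),), flags=flags))
    return spans


def identify_rna_subunits(structure: StructureModel) -> list[SubunitSpan]:
    """One whole-chain subunit per RNA chain; hybrid chains yield nothing
    and are reported."""
    spans = []
    for chain in structure.chains:
        if chain.polymer_kind == "rna":
            spans.append(SubunitSpan(
                subunit_kind="rna", chain_id=chain.chain_id,
                segments=((0, len(chain.units) - 1),)))
        elif chain.polymer_kind == "hybrid":
            logger.warning("chain %s mixes DNA and RNA bases; excluded",
                           chain.chain_id)
    return spans


# ---------------------------------------------------------------------------
# full annotation

def annotate_structure(structure: StructureModel,
                       assignments: Iterable[DomainAssignment] = (),
                       params: AnnotationParams = AnnotationParams(),
                       report: Optional[list] = None) -> list[SubunitSpan]:
    """Assign every chain region of a structure to one of the eight subunit
    types and label the spans chain-by-chain in sequence order.

    Stages: nucleic subunits (DNA pairing rule, RNA chains), then per
    protein chain domain mapping, unstructured-region classification, and
    the peptide / undefined-chain rule for undomained chains.  Hybrid and
    non-macromolecular chains are skipped (reported via ``report`` when
    given).
    """
    assignments = list(assignments)
    spans: list[SubunitSpan] = []
    spans.extend(identify_dna_subunits(structure))
    spans.extend(identify_rna_subunits(structure))
    for chain in structure.chains:
        if chain.polymer_kind == "hybrid" and report is not None:
            report.append(f"chain {chain.chain_id}: hybrid; excluded")
        if chain.polymer_kind != "protein":
            continue
        domains, rejects = resolve_domains(chain, assignments)
        if report is not None:
            report.extend(rejects)
        for r in rejects:
            logger.warning("%s", r)
        if domains:
            chain_spans = domains + annotate_unstructured(chain, domains)
        else:
            chain_spans = [classify_undomained_chain(chain, params)]
        spans.extend(chain_spans)

    # stable per-chain labels: chain letter + 1-based ordinal along sequence
    labeled: list[SubunitSpan] = []
    by_chain: dict[str, list[SubunitSpan]] = {}
    for span in spans:
        by_chain.setdefault(span.chain_id, []).append(span)
    for chain in structure.chains:
        chain_spans = sorted(by_chain.get(chain.chain_id, []),
                             key=lambda s: s.start_index)
        for ordinal, span in enumerate(chain_spans, start=1):
            labeled.append(replace(span, label=f"{span.chain_id}{ordinal}"))
    return labeled
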