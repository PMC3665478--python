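"""Readers and writers for every external representation the tool touches.

Sequences (FASTA or raw), variant tokens and labeled variant tables, the Gene
Ontology (OBO 1.2), protein structures (PDB coordinate format), per-residue
solvent accessibility (DSSP output or a two-column fallback), PANTHER output
adapters, and trained-model files with a versioned magic header.

All sequence positions are 1-based at every interface.
"""

from __future__ import annotations

import io
import pickle
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

import networkx as nx
import numpy as np
import obonet
from Bio import SeqIO
from Bio.PDB import PDBParser

from .errors import (
    CompatibilityError,
    ConfigError,
    FormatError,
    IntegrityError,
    LookupFailure,
)
from .residues import VALID_SEQUENCE_CHARS

Source = Union[str, TextIO]


def _as_stream(source: Source) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


# ---------------------------------------------------------------------------
# Sequences and variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise IntegrityError("protein record requires a non-empty id")
        if not self.sequence:
            raise IntegrityError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """One-letter residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise LookupFailure(
                f"position {pos} outside protein {self.id} (length {len(self)})"
            )
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class VariantRecord:
    """One single-residue substitution on one protein.

    ``label`` is ``"Disease"``, ``"Neutral"`` or ``None`` (unlabeled query).
    """

    protein_id: str
    wt: str
    pos: int
    mut: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wt == self.mut:
            raise FormatError(
                f"identity substitution {self.wt}{self.pos}{self.mut}"
            )
        if self.pos < 1:
            raise FormatError(f"positions are 1-based, got {self.pos}")
        if self.label not in (None, "Disease", "Neutral"):
            raise FormatError(f"unknown label {self.label!r}")

    @property
    def token(self) -> str:
        return f"{self.wt}{self.pos}{self.mut}"

    def resolve(self, protein: ProteinRecord) -> None:
        """Raise unless the protein carries ``wt`` at ``pos``."""
        found = protein.residue(self.pos)
        if found != self.wt:
            raise IntegrityError(
                f"{self.protein_id} {self.token}: sequence has {found} at "
                f"position {self.pos}, variant claims {self.wt}"
            )


_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_variant(token: str) -> tuple[str, int, str]:
    """Parse a ``wtPOSmut`` token such as ``A52V`` (case-insensitive)."""
    m = _VARIANT_RE.match(token.strip())
    if m is None:
        raise FormatError(f"cannot parse variant token {token!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt == mut:
        raise FormatError(f"identity substitution in token {token!r}")
    if pos == 0:
        raise FormatError(f"position 0 in token {token!r}: positions are 1-based")
    return wt, pos, mut


def read_fasta(source: Source) -> list[ProteinRecord]:
    """Read FASTA or a single raw sequence block.

    Sequences are uppercased and whitespace-stripped; characters outside the
    20 standard residues plus X/B/Z/U are rejected with the offending
    character and line number.
    """
    text = _as_stream(source).read()
    if not text.strip():
        return []
    records: list[ProteinRecord] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            seq = str(rec.seq).upper().replace(" ", "")
            _validate_sequence(seq, rec.id)
            records.append(ProteinRecord(id=rec.id, sequence=seq))
    else:
        seq = "".join(text.split()).upper()
        _validate_sequence(seq, "raw input")
        records.append(ProteinRecord(id="query_1", sequence=seq))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise IntegrityError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def _validate_sequence(seq: str, name: str) -> None:
    if not seq:
        raise FormatError(f"{name}: empty sequence")
    for i, ch in enumerate(seq):
        if ch not in VALID_SEQUENCE_CHARS:
            raise FormatError(
                f"{name}: illegal sequence character {ch!r} at position {i + 1}"
            )


def write_fasta(records: Iterable[ProteinRecord], width: int = 60) -> str:
    out: list[str] = []
    for rec in records:
        out.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), width):
            out.append(rec.sequence[i : i + width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Labeled variant datasets
# ---------------------------------------------------------------------------

#: Default mapping from source-file label vocabulary to the two classes.
DEFAULT_LABEL_MAP: dict[str, str] = {
    "disease": "Disease",
    "d": "Disease",
    "pathogenic": "Disease",
    "neutral": "Neutral",
    "n": "Neutral",
    "polymorphism": "Neutral",
}


@dataclass
class SapDialect:
    """Column mapping for delimited variant-dataset files.

    When ``sniff_header`` is left on, the column indices are located from the
    header line by name; explicit indices override sniffing.
    """

    delimiter: str = "\t"
    protein_col: Optional[int] = None
    variant_col: Optional[int] = None
    label_col: Optional[int] = None
    label_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    sniff_header: bool = True

    _PROTEIN_NAMES = ("protein", "protein_id", "acc", "accession", "swissprot", "id")
    _VARIANT_NAMES = ("variant", "variation", "mutation", "sap", "aa_change")
    _LABEL_NAMES = ("label", "effect", "type", "class", "annotation")

    def locate(self, header: list[str]) -> tuple[int, int, int]:
        def find(names: tuple[str, ...], what: str, explicit: Optional[int]) -> int:
            if explicit is not None:
                return explicit
            lowered = [h.strip().lower() for h in header]
            for name in names:
                if name in lowered:
                    return lowered.index(name)
            raise ConfigError(
                f"cannot locate mandatory {what} column in header {header!r}"
            )

        return (
            find(self._PROTEIN_NAMES, "protein", self.protein_col),
            find(self._VARIANT_NAMES, "variant", self.variant_col),
            find(self._LABEL_NAMES, "label", self.label_col),
        )


@dataclass
class DatasetTable:
    """A fully labeled variant dataset plus row-level diagnostics."""

    records: list[VariantRecord]
    provenance: str = ""
    structure_map: dict[tuple[str, str], tuple[str, str, int]] = field(
        default_factory=dict
    )
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.label is None:
                raise IntegrityError(
                    f"dataset {self.provenance!r}: unlabeled record {rec.token}"
                )
        for key in self.structure_map:
            if key not in {(r.protein_id, r.token) for r in self.records}:
                raise IntegrityError(f"structure_map key {key} not in records")

    def class_counts(self) -> tuple[int, int]:
        """(n_disease, n_neutral)."""
        d = sum(1 for r in self.records if r.label == "Disease")
        return d, len(self.records) - d

    def proteins(self) -> set[str]:
        return {r.protein_id for r in self.records}


def read_sap_dataset(
    source: Source,
    dialect: Optional[SapDialect] = None,
    provenance: str = "",
) -> DatasetTable:
    """Parse a delimited variant table into labeled records.

    Rows whose variant token or label cannot be parsed are collected into the
    table's ``skipped`` diagnostics (line number + reason), never silently
    dropped.
    """
    dialect = dialect or SapDialect()
    lines = _as_stream(source).read().splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        return DatasetTable(records=[], provenance=provenance)
    header = lines[0].split(dialect.delimiter)
    p_col, v_col, l_col = dialect.locate(header)
    records: list[VariantRecord] = []
    skipped: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(dialect.delimiter)
        try:
            protein_id = fields[p_col].strip()
            wt, pos, mut = parse_variant(fields[v_col].strip())
            raw_label = fields[l_col].strip().lower()
        except (IndexError, FormatError) as exc:
            skipped.append((lineno, str(exc)))
            continue
        if raw_label not in dialect.label_map:
            skipped.append((lineno, f"unmapped label {fields[l_col].strip()!r}"))
            continue
        records.append(
            VariantRecord(protein_id, wt, pos, mut, dialect.label_map[raw_label])
        )
    return DatasetTable(records=records, provenance=provenance, skipped=skipped)


def write_sap_dataset(table: DatasetTable) -> str:
    out = ["protein\tvariant\tlabel"]
    for rec in table.records:
        out.append(f"{rec.protein_id}\t{rec.token}\t{rec.label}")
    return "\n".join(out) + "\n"


def resolve_dataset(
    table: DatasetTable, proteins: dict[str, ProteinRecord]
) -> list[tuple[VariantRecord, str]]:
    """Check every record against its protein sequence.

    Returns the rejection report: (record, reason) pairs for records whose
    claimed wild type disagrees with the sequence or whose protein is missing.
    Violations are reported, never repaired.
    """
    rejected: list[tuple[VariantRecord, str]] = []
    for rec in table.records:
        prot = proteins.get(rec.protein_id)
        if prot is None:
            rejected.append((rec, f"unknown protein {rec.protein_id}"))
            continue
        try:
            rec.resolve(prot)
        except (IntegrityError, LookupFailure) as exc:
            rejected.append((rec, str(exc)))
    return rejected


# ---------------------------------------------------------------------------
# Gene Ontology
# ---------------------------------------------------------------------------

CLOSURE_RELATIONS = ("is_a", "part_of")


@dataclass
class GoGraph:
    """The GO DAG restricted to is_a / part_of child->parent edges."""

    graph: nx.DiGraph  # edge u -> v means u is_a/part_of v
    namespaces: dict[str, str] = field(default_factory=dict)
    obsolete: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise IntegrityError("GO graph contains a cycle over is_a/part_of")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def parents(self, term: str, relations: tuple[str, ...] = CLOSURE_RELATIONS) -> set[str]:
        return {
            v
            for _, v, rel in self.graph.out_edges(term, data="relation")
            if rel in relations
        }


def read_obo(source: Source) -> GoGraph:
    """Load an OBO 1.2 ontology, keeping is_a and part_of edges.

    Obsolete terms are flagged and excluded from closures by default.
    """
    raw = obonet.read_obo(_as_stream(source), ignore_obsolete=False)
    graph = nx.DiGraph()
    namespaces: dict[str, str] = {}
    obsolete: set[str] = set()
    for node, data in raw.nodes(data=True):
        graph.add_node(node)
        namespaces[node] = data.get("namespace", "")
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
    for u, v, rel in raw.edges(keys=True):
        if rel in CLOSURE_RELATIONS:
            if v not in graph:
                raise IntegrityError(f"edge endpoint {v} is not a known term")
            graph.add_edge(u, v, relation=rel)
    return GoGraph(graph=graph, namespaces=namespaces, obsolete=frozenset(obsolete))


def write_obo(go: GoGraph) -> str:
    """Serialize a GoGraph back to minimal OBO 1.2 (fixture round-trips)."""
    out = ["format-version: 1.2", ""]
    for term in sorted(go.terms):
        out.append("[Term]")
        out.append(f"id: {term}")
        out.append(f"name: {term}")
        ns = go.namespaces.get(term)
        if ns:
            out.append(f"namespace: {ns}")
        if term in go.obsolete:
            out.append("is_obsolete: true")
        for _, parent, rel in sorted(go.graph.out_edges(term, data="relation")):
            if rel == "is_a":
                out.append(f"is_a: {parent}")
            else:
                out.append(f"relationship: {rel} {parent}")
        out.append("")
    return "\n".join(out) + "\n"


def read_annotations(source: Source) -> dict[str, set[str]]:
    """Two-column (protein_id, GO id) tab-separated annotation file."""
    annotations: dict[str, set[str]] = {}
    for lineno, line in enumerate(_as_stream(source).read().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"annotation line {lineno}: expected 2 columns")
        annotations.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return annotations


def write_annotations(annotations: dict[str, set[str]]) -> str:
    out = []
    for pid in sorted(annotations):
        for term in sorted(annotations[pid]):
            out.append(f"{pid}\t{term}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Protein structures
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One structure residue: PDB number (+insertion code), type and atoms."""

    number: int
    icode: str
    name: str  # 3-letter residue type
    atoms: dict[str, np.ndarray]

    @property
    def ca(self) -> Optional[np.ndarray]:
        return self.atoms.get("CA")

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class StructureModel:
    """First-model protein coordinates, HETATM excluded, chains ordered."""

    chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        for chain_id, residues in self.chains.items():
            seen: set[tuple[int, str]] = set()
            for res in residues:
                if res.key in seen:
                    raise IntegrityError(
                        f"chain {chain_id}: duplicate residue {res.number}{res.icode}"
                    )
                seen.add(res.key)
                for name, coord in res.atoms.items():
                    if not np.all(np.isfinite(coord)):
                        raise IntegrityError(
                            f"non-finite coordinate for {chain_id}/{res.number}/{name}"
                        )

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise LookupFailure(
                f"chain {chain_id!r} absent; available: {sorted(self.chains)}"
            )
        return self.chains[chain_id]

    def residue(self, chain_id: str, number: int, icode: str = " ") -> Residue:
        for res in self.chain(chain_id):
            if res.number == number and res.icode == icode:
                return res
        raise LookupFailure(f"residue {number}{icode.strip()} absent from chain {chain_id}")

    def all_residues(self) -> Iterable[tuple[str, Residue]]:
        for chain_id, residues in self.chains.items():
            for res in residues:
                yield chain_id, res


def read_structure(source: Source) -> StructureModel:
    """Parse PDB coordinate records.

    First model only; HETATM excluded; disordered atoms resolved to the
    highest-occupancy altloc (ties broken alphabetically).
    """
    stream = _as_stream(source)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", stream)
    models = list(structure.get_models())
    if not models:
        raise FormatError("no ATOM records found")
    model = models[0]
    chains: dict[str, list[Residue]] = {}
    n_atoms = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            hetflag, resnum, icode = res.id
            if hetflag != " ":
                continue  # HETATM / water
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.is_disordered():
                    children = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-a.get_occupancy(), a.get_altloc()),
                    )
                    chosen = children[0]
                else:
                    chosen = atom
                atoms[atom.get_id()] = np.asarray(chosen.get_coord(), dtype=float)
                n_atoms += 1
            residues.append(
                Residue(number=resnum, icode=icode, name=res.get_resname(), atoms=atoms)
            )
        if residues:
            chains[chain.id] = residues
    if n_atoms == 0:
        raise FormatError("no ATOM records found")
    return StructureModel(chains=chains)


def write_structure(model: StructureModel) -> str:
    """Serialize to PDB ATOM records (fixture round-trips)."""
    lines: list[str] = []
    serial = 1
    for chain_id in model.chains:
        for res in model.chains[chain_id]:
            for atom_name, coord in res.atoms.items():
                name_field = f" {atom_name:<3s}" if len(atom_name) < 4 else atom_name
                lines.append(
                    f"ATOM  {serial:5d} {name_field:<4s} {res.name:>3s} "
                    f"{chain_id}{res.number:4d}{res.icode:1s}   "
                    f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}           "
                    f"{atom_name[0]:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityRecord:
    """Absolute accessible surface area (A^2) keyed by (chain, residue number)."""

    acc: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.acc.items():
            if value < 0:
                raise IntegrityError(f"negative accessibility for {key}")

    def get(self, chain: str, number: int) -> Optional[float]:
        return self.acc.get((chain, number))


def read_accessibility(source: Source) -> AccessibilityRecord:
    """Read per-residue absolute ASA from DSSP output or the two-column dialect.

    The fallback dialect is one ``chain:resnum<TAB-or-space>ACC`` pair per
    line.  A residue listed twice is an integrity error.
    """
    text = _as_stream(source).read()
    if "  #  RESIDUE" in text:
        return _read_dssp(text)
    acc: dict[tuple[str, int], float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            key_part, value_part = line.split()
            chain, resnum = key_part.split(":")
            key = (chain, int(resnum))
            value = float(value_part)
        except ValueError as exc:
            raise FormatError(f"accessibility line {lineno}: {exc}") from exc
        if key in acc:
            raise IntegrityError(f"residue {key} listed twice")
        acc[key] = value
    return AccessibilityRecord(acc=acc)


def _read_dssp(text: str) -> AccessibilityRecord:
    acc: dict[tuple[str, int], float] = {}
    in_table = False
    for line in text.splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 38:
            continue
        resnum_field = line[5:10].strip()
        if not resnum_field:  # chain break
            continue
        chain = line[11]
        key = (chain, int(resnum_field))
        if key in acc:
            raise IntegrityError(f"residue {key} listed twice in DSSP file")
        acc[key] = float(line[34:38])
    return AccessibilityRecord(acc=acc)


def write_accessibility(record: AccessibilityRecord) -> str:
    """Serialize to the documented two-column fallback dialect."""
    out = [
        f"{chain}:{resnum}\t{value:.1f}"
        for (chain, resnum), value in sorted(record.acc.items())
    ]
    return "\n".join(out) + "\n"


def write_dssp_like(record: AccessibilityRecord, residue_types: dict[tuple[str, int], str]) -> str:
    """Emit a minimal DSSP-format table (fixture generation only)."""
    out = [
        "==== Secondary Structure Definition (synthetic fixture) ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
    ]
    for i, ((chain, resnum), value) in enumerate(sorted(record.acc.items()), start=1):
        aa = residue_types.get((chain, resnum), "A")
        # pad so ACC occupies columns 34-38 as in real DSSP output
        out.append(f"{i:5d}{resnum:5d} {chain} {aa}" + " " * 20 + f"{value:4.0f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PANTHER adapter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PantherRecord:
    """Per-variant external-predictor outputs used as four input features."""

    p_deleterious: float
    f_wt: float
    f_mut: float
    n_independent_counts: float

    def __post_init__(self) -> None:
        for name in ("p_deleterious", "f_wt", "f_mut", "n_independent_counts"):
            if not np.isfinite(getattr(self, name)):
                raise IntegrityError(f"non-finite PANTHER field {name}")
        if not 0.0 <= self.p_deleterious <= 1.0:
            raise IntegrityError(
                f"p_deleterious {self.p_deleterious} outside [0,1]"
            )
        if self.n_independent_counts < 0:
            raise IntegrityError("n_independent_counts must be >= 0")


def read_panther(source: Source) -> dict[tuple[str, str], PantherRecord]:
    """Tab-separated PANTHER output adapter.

    Columns: protein_id, variant token, P(deleterious), f_wt, f_mut, n_counts.
    """
    records: dict[tuple[str, str], PantherRecord] = {}
    lines = _as_stream(source).read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#") or line.lower().startswith("protein"):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise FormatError(f"PANTHER line {lineno}: expected 6 columns")
        key = (parts[0].strip(), parts[1].strip().upper())
        records[key] = PantherRecord(
            p_deleterious=float(parts[2]),
            f_wt=float(parts[3]),
            f_mut=float(parts[4]),
            n_independent_counts=float(parts[5]),
        )
    return records


def write_panther(records: dict[tuple[str, str], PantherRecord]) -> str:
    out = ["protein\tvariant\tp_deleterious\tf_wt\tf_mut\tn_counts"]
    for (pid, token), rec in sorted(records.items()):
        out.append(
            f"{pid}\t{token}\t{rec.p_deleterious:.6g}\t{rec.f_wt:.6g}"
            f"\t{rec.f_mut:.6g}\t{rec.n_independent_counts:.6g}"
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Cluster files
# ---------------------------------------------------------------------------

def read_clusters(source: Source) -> dict[str, str]:
    """Two-column (protein_id, cluster_id) tab-separated cluster file."""
    clusters: dict[str, str] = {}
    for lineno, line in enumerate(_as_stream(source).read().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"cluster line {lineno}: expected 2 columns")
        clusters[parts[0].strip()] = parts[1].strip()
    return clusters


def write_clusters(clusters: dict[str, str]) -> str:
    return "\n".join(f"{p}\t{c}" for p, c in sorted(clusters.items())) + "\n"


# ---------------------------------------------------------------------------
# Trained-model files
# ---------------------------------------------------------------------------

MODEL_MAGIC = b"SAPGO-MODEL/1\n"


def save_model(model, path: str) -> None:
    """Serialize a trained model with a versioned magic header."""
    payload = pickle.dumps(model, protocol=4)
    with open(path, "wb") as fh:
        fh.write(MODEL_MAGIC)
        fh.write(payload)


def load_model(path: str):
    """Load a model file, rejecting unknown formats."""
    with open(path, "rb") as fh:
        magic = fh.read(len(MODEL_MAGIC))
        if magic != MODEL_MAGIC:
            raise CompatibilityError(
                f"{path}: not a recognized model file (bad magic header)"
            )
        return pickle.loads(fh.read())
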