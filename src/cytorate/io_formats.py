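"""Domain types and file formats.

The pipeline compares the two subgenomes of an allotetraploid against their
closest diploid relatives and an outgroup, so every sequence must resolve to
one of four species roles; polyploid sequences additionally carry a
maternal/paternal subgenome tag when their identifier encodes a chromosome.
This module owns those role conventions plus the FASTA / newick / tabular
readers and writers every other stage builds on.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import MISSING, STOP_CODONS, codon_state, translate_codon

logger = logging.getLogger("cytorate")

# ---------------------------------------------------------------------------
# species roles


class Role:
    OUTGROUP = "outgroup"
    DIPLOID_MATERNAL = "diploid_maternal"
    DIPLOID_PATERNAL = "diploid_paternal"
    POLYPLOID = "polyploid"

    ALL = (OUTGROUP, DIPLOID_MATERNAL, DIPLOID_PATERNAL, POLYPLOID)


class Subgenome:
    MATERNAL = "maternal"
    PATERNAL = "paternal"


#: the five per-sequence roles of a complete quintet
QUINTET_ROLES = (
    Role.OUTGROUP,
    Role.DIPLOID_MATERNAL,
    Role.DIPLOID_PATERNAL,
    "polyploid_maternal",
    "polyploid_paternal",
)


class RoleResolutionError(KeyError):
    """A sequence identifier could not be assigned to a species role."""


@dataclasses.dataclass(frozen=True)
class RoleLabel:
    role: str
    subgenome: str | None = None

    @property
    def quintet_role(self) -> str:
        if self.role == Role.POLYPLOID:
            if self.subgenome is None:
                raise ValueError("polyploid sequence lacks a subgenome tag")
            return f"polyploid_{self.subgenome}"
        return self.role


@dataclasses.dataclass(frozen=True)
class IdRule:
    """Rule extracting a species tag (and polyploid subgenome) from an id.

    ``pattern`` must define a named group ``tag``; an optional named group
    ``chrom`` captures a chromosome code that ``subgenome_by_chrom`` maps to
    'maternal' or 'paternal' for polyploid sequences.
    """

    pattern: str = r"^(?P<tag>[^_]+)_(?P<chrom>[A-Za-z])?"
    subgenome_by_chrom: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def parse(self, seq_id: str) -> tuple[str, str | None]:
        m = re.match(self.pattern, seq_id)
        if not m:
            raise RoleResolutionError(f"id {seq_id!r} does not match the id rule")
        tag = m.group("tag")
        chrom = m.groupdict().get("chrom")
        return tag, chrom


@dataclasses.dataclass(frozen=True)
class SpeciesMap:
    """Mapping from the four species roles to species tags, plus the id rule."""

    roles: Mapping[str, str]
    id_rule: IdRule = dataclasses.field(default_factory=IdRule)

    def __post_init__(self):
        missing = set(Role.ALL) - set(self.roles)
        if missing:
            raise ValueError(f"species map lacks roles: {sorted(missing)}")
        tags = list(self.roles.values())
        if len(set(tags)) != 4:
            raise ValueError("species tags must be four distinct values")

    @property
    def tag_to_role(self) -> dict[str, str]:
        return {tag: role for role, tag in self.roles.items()}

    def resolve(self, seq_id: str) -> RoleLabel:
        tag, chrom = self.id_rule.parse(seq_id)
        role = self.tag_to_role.get(tag)
        if role is None:
            raise RoleResolutionError(
                f"id {seq_id!r}: species tag {tag!r} is not in the species map"
            )
        if role == Role.POLYPLOID and chrom is not None:
            sub = self.id_rule.subgenome_by_chrom.get(chrom)
            return RoleLabel(role, sub)
        return RoleLabel(role)


def resolve_roles(obj, species_map: SpeciesMap) -> dict[str, RoleLabel]:
    """Label every sequence id of an alignment or tree with its species role."""
    if isinstance(obj, CodonAlignment):
        ids = list(obj.ids)
    elif isinstance(obj, GeneTree):
        ids = obj.tip_labels()
    else:
        ids = list(obj)
    return {i: species_map.resolve(i) for i in ids}


# ---------------------------------------------------------------------------
# codon alignments


class AlignmentError(ValueError):
    pass


class FrameError(AlignmentError):
    pass


_ALPHABET = set("ACGTN-")


class CodonAlignment:
    """An in-frame aligned set of CDS sequences.

    All sequences share the same column count (a multiple of 3).  Codons
    containing '-' or 'N' are treated as missing data throughout the package.
    A trailing stop codon (in any sequence) causes the final codon column to
    be stripped; internal stop codons are rejected.
    """

    def __init__(self, ids: Iterable[str], seqs: Iterable[str], *, validate: bool = True):
        self.ids = list(ids)
        self.seqs = [s.upper() for s in seqs]
        if validate:
            self._validate()

    def _validate(self):
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if not self.seqs:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} is not a multiple of 3")
        bad = set("".join(self.seqs)) - _ALPHABET
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")
        self._strip_terminal_stops()
        for sid, seq in zip(self.ids, self.seqs):
            for k in range(0, len(seq), 3):
                codon = seq[k : k + 3]
                if codon in STOP_CODONS:
                    raise AlignmentError(
                        f"internal stop codon {codon} at column {k} in {sid!r}"
                    )

    def _strip_terminal_stops(self):
        while self.seqs[0]:
            tail = [s[-3:] for s in self.seqs]
            if any(c in STOP_CODONS for c in tail):
                self.seqs = [s[:-3] for s in self.seqs]
            else:
                break

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def codon_states(self) -> np.ndarray:
        """(n_seqs, n_codons) int array of 61-state indices; MISSING for gaps/N."""
        out = np.empty((len(self.seqs), self.n_codons), dtype=np.int64)
        for r, seq in enumerate(self.seqs):
            out[r] = [codon_state(seq[k : k + 3]) for k in range(0, len(seq), 3)]
        return out

    def amino_acids(self) -> list[str]:
        """Translated sequences; 'X' marks codons with gaps or ambiguity."""
        return [
            "".join(translate_codon(s[k : k + 3]) for k in range(0, len(s), 3))
            for s in self.seqs
        ]

    def ungapped_lengths(self) -> dict[str, int]:
        return {i: len(s) - s.count("-") for i, s in zip(self.ids, self.seqs)}

    def select(self, ids: Iterable[str]) -> "CodonAlignment":
        ids = list(ids)
        return CodonAlignment(ids, [self.sequence(i) for i in ids], validate=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CodonAlignment)
            and self.ids == other.ids
            and self.seqs == other.seqs
        )


def read_fasta(path) -> CodonAlignment:
    """Read an aligned FASTA file into a validated CodonAlignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    aln = CodonAlignment([r.id for r in records], [str(r.seq) for r in records])
    logger.info("read %d sequences x %d columns from %s", len(aln), aln.length, path)
    return aln


def write_fasta(aln: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene trees


class TreeFormatError(ValueError):
    pass


class GeneTree:
    """A gene tree with optional integer bootstrap supports on internal splits.

    Thin wrapper around a dendropy tree; supports are carried as internal
    node labels, branch lengths as edge lengths.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise TreeFormatError("duplicate tip labels")
        for s in self.supports().values():
            if not 0 <= s <= 100:
                raise TreeFormatError(f"support {s} outside [0, 100]")

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeFormatError(f"newick parse error: {exc}") from exc
        return cls(tree)

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def supports(self) -> dict[int, int]:
        """Support per internal (non-root, non-leaf) node, keyed by node id."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            if node.label is not None and str(node.label).strip():
                out[id(node)] = int(float(node.label))
        return out

    def branch_lengths(self) -> dict[str, float]:
        """Lengths on terminal branches, keyed by tip label (where present)."""
        return {
            leaf.taxon.label: leaf.edge.length
            for leaf in self.tree.leaf_node_iter()
            if leaf.edge.length is not None
        }

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def clone(self) -> "GeneTree":
        return GeneTree(self.tree.clone(depth=1))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial tip-label splits, as the smaller side of each split."""
        labels = set(self.tip_labels())
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(clade) < len(labels):
                other = frozenset(labels - clade)
                out.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
        return out


def read_newick(path) -> GeneTree:
    text = Path(path).read_text()
    return GeneTree.from_newick(text)


def read_newick_list(path) -> list[GeneTree]:
    """Read a multi-tree newick file (one tree per line/semicolon)."""
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeFormatError(f"newick parse error: {exc}") from exc
    return [GeneTree(t) for t in trees]


def write_newick(tree: GeneTree, path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide knobs; see docs/methods.md for rationale and units."""

    seed: int = 1
    ds_cutoff: float = 2.0  # maximum tree-wide dS per quintet (per dataset)
    bootstrap_reps: int = 1000
    optimizer_replicates: int = 5
    support_collapse_threshold: int = 50
    cri_threshold: float = 0.5

    def __post_init__(self):
        if self.seed <= 0 or self.bootstrap_reps <= 0 or self.optimizer_replicates <= 0:
            raise ValueError("seed, bootstrap_reps, optimizer_replicates must be positive")
        if self.ds_cutoff <= 0 or self.support_collapse_threshold <= 0:
            raise ValueError("ds_cutoff and support_collapse_threshold must be positive")
        if not 0 <= self.cri_threshold <= 1:
            raise ValueError("cri_threshold must lie in [0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain-text key=value config file."""
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def read_species_map(path) -> SpeciesMap:
    """Parse a plain-text species map.

    Lines are key=value: the four role keys (outgroup, diploid_maternal,
    diploid_paternal, polyploid) give species tags; optional
    ``subgenome.<CHROM>=maternal|paternal`` lines map polyploid chromosome
    codes to subgenomes; an optional ``id_pattern`` overrides the default
    identifier regex.
    """
    roles: dict[str, str] = {}
    chrom_map: dict[str, str] = {}
    pattern = IdRule.pattern
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed species map line: {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in Role.ALL:
            roles[key] = value
        elif key.startswith("subgenome."):
            chrom_map[key.split(".", 1)[1]] = value
        elif key == "id_pattern":
            pattern = value
        else:
            raise ValueError(f"unknown species map key: {key!r}")
    return SpeciesMap(
        roles=roles, id_rule=IdRule(pattern=pattern, subgenome_by_chrom=chrom_map)
    )


def log_stage(stage: str, read: int, retained: int) -> None:
    """Per-stage record count logging (read / retained / excluded)."""
    logger.info(
        "%s: read=%d retained=%d excluded=%d", stage, read, retained, read - retained
    )
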