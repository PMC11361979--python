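"""Lineage-specific amino-acid-change calling from a labeled protein MSA.

Given an alignment containing an X-haplotype sequence, a Y-haplotype
sequence and at least two outgroup species (each possibly represented by
several isoforms), each column is compared against the outgroup
consensus and classified: a change carried by both X and Y (shared
derived), a change on X only, a change on Y only, or an indel event.
Substitutions are scored conservative/non-conserved against a
substitution matrix (BLOSUM62 by default, threshold score >= 0).

Columns where the outgroups themselves disagree are skipped as not
well-conserved, and columns where the outgroups are entirely gapped
(insertions relative to the outgroups) are not called.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import substitution_matrices

GAP = "-"

SHARED_DERIVED = "SHARED_DERIVED"
X_SPECIFIC = "X_SPECIFIC"
Y_SPECIFIC = "Y_SPECIFIC"
INDEL = "INDEL"


def load_matrix(name_or_path: str = "BLOSUM62"):
    """Load a substitution matrix by Biopython name or from a text file."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        return substitution_matrices.read(name_or_path)


@dataclasses.dataclass
class LabeledAlignment:
    """Equal-length gapped sequences with X/Y/outgroup roles.

    ``species`` groups outgroup isoforms: isoforms of one species count
    as a single witness when forming the outgroup consensus.
    """

    ids: list[str]
    seqs: dict[str, str]
    roles: dict[str, str]
    species: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(self.seqs[i]) for i in self.ids}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        by_role = {"X": 0, "Y": 0, "outgroup": 0}
        for i in self.ids:
            role = self.roles.get(i)
            if role not in by_role:
                raise ValueError(f"sequence {i!r} has unknown role {role!r}")
            by_role[role] += 1
        if by_role["X"] < 1 or by_role["Y"] < 1 or by_role["outgroup"] < 2:
            raise ValueError(
                "alignment needs >=1 X, >=1 Y and >=2 outgroup sequences, got "
                f"{by_role}"
            )

    @property
    def length(self) -> int:
        return len(self.seqs[self.ids[0]])

    def role_ids(self, role: str) -> list[str]:
        return [i for i in self.ids if self.roles[i] == role]

    @classmethod
    def from_dicts(
        cls,
        sequences: Mapping[str, str],
        roles: Mapping[str, str],
        species: Mapping[str, str] | None = None,
    ) -> "LabeledAlignment":
        ids = list(sequences)
        sp = dict(species) if species else {i: i for i in ids}
        for i in ids:
            sp.setdefault(i, i)
        return cls(ids=ids, seqs=dict(sequences), roles=dict(roles), species=sp)

    @classmethod
    def from_fasta(cls, aln_path: str | Path, roles_path: str | Path) -> "LabeledAlignment":
        """Read an aligned FASTA plus a roles TSV (id, role[, species])."""
        roles: dict[str, str] = {}
        species: dict[str, str] = {}
        with open(roles_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                roles[parts[0]] = parts[1]
                if len(parts) > 2 and parts[2]:
                    species[parts[0]] = parts[2]
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(aln_path), "fasta")}
        missing = set(seqs) - set(roles)
        if missing:
            raise ValueError(f"sequences without a role: {sorted(missing)}")
        return cls.from_dicts(seqs, roles, species)


@dataclasses.dataclass
class ColumnCall:
    """One called change.

    ``column`` is the 1-based alignment column where the event starts;
    ``position`` the 1-based residue index in the ungapped X sequence
    (for a deletion on X, the index the residue would occupy).  INDEL
    events carry the sequence bearing the gap in ``indel_on`` and span
    ``n_columns`` merged columns.
    """

    column: int
    position: int
    category: str
    outgroup_consensus: str
    x_residue: str
    y_residue: str
    conservative: bool
    notation: str
    indel_on: str | None = None
    n_columns: int = 1


def outgroup_consensus(
    residues: Sequence[str] | Mapping[str, Iterable[str]], min_support: float = 1.0
) -> str | None:
    """Consensus residue of the outgroups at one column, or None (skip).

    ``residues`` is either a flat sequence of per-sequence residues or a
    mapping species -> isoform residues; a species supports a candidate
    when any of its isoforms carries it.  Returns the residue supported
    by at least ``min_support`` of species with non-gap residues; None
    when no candidate reaches support or all outgroups are gapped.
    """
    if isinstance(residues, Mapping):
        groups = {sp: {r for r in rs if r != GAP} for sp, rs in residues.items()}
    else:
        groups = {str(i): ({r} if r != GAP else set()) for i, r in enumerate(residues)}
    informative = [rs for rs in groups.values() if rs]
    if len(informative) < 2:
        return None  # all-gap or nearly all-gap column: not assessable
    candidates = sorted(set().union(*informative))
    best: str | None = None
    best_support = 0.0
    for cand in candidates:
        support = sum(1 for rs in informative if cand in rs) / len(informative)
        if support > best_support:
            best, best_support = cand, support
    if best_support >= min_support:
        return best
    return None


def _role_residue(aln: LabeledAlignment, ids: list[str], col: int) -> str | None:
    """Residue of a role at a column; None when the role's sequences disagree."""
    chars = {aln.seqs[i][col] for i in ids}
    if len(chars) != 1:
        return None
    return next(iter(chars))


def _is_conservative(matrix, a: str, b: str, threshold: float) -> bool:
    try:
        return float(matrix[a, b]) >= threshold
    except (KeyError, IndexError):
        return False


class _IndelRun:
    def __init__(self, target: str, column: int, position: int):
        self.target = target  # "X" or "Y"
        self.column = column
        self.position = position
        self.residues: list[str] = []

    def call(self) -> ColumnCall:
        notation = ", ".join(
            f"{res}{self.position + i}Del" for i, res in enumerate(self.residues)
        )
        return ColumnCall(
            column=self.column,
            position=self.position,
            category=INDEL,
            outgroup_consensus=self.residues[0],
            x_residue=GAP if self.target == "X" else self.residues[0],
            y_residue=GAP if self.target == "Y" else self.residues[0],
            conservative=False,
            notation=notation,
            indel_on=self.target,
            n_columns=len(self.residues),
        )


def classify_columns(
    aln: LabeledAlignment,
    matrix=None,
    min_support: float = 1.0,
    conservative_threshold: float = 0.0,
) -> list[ColumnCall]:
    """Classify every alignment column against the outgroup consensus.

    Emits SHARED_DERIVED / X_SPECIFIC / Y_SPECIFIC substitution calls
    (a column where X and Y carry two different derived residues yields
    one X_SPECIFIC and one Y_SPECIFIC call) and run-merged INDEL events.
    Substitution notation is consensus+position+derived, e.g. "P76S";
    positions follow the ungapped X sequence.
    """
    if matrix is None:
        matrix = load_matrix("BLOSUM62")
    x_ids = aln.role_ids("X")
    y_ids = aln.role_ids("Y")
    out_ids = aln.role_ids("outgroup")

    calls: list[ColumnCall] = []
    runs: dict[str, _IndelRun] = {}

    def close(target: str) -> None:
        run = runs.pop(target, None)
        if run is not None:
            calls.append(run.call())

    x_pos = 0  # ungapped X residues consumed
    for col in range(aln.length):
        x = _role_residue(aln, x_ids, col)
        y = _role_residue(aln, y_ids, col)
        x_gap = x == GAP
        if x is not None and not x_gap:
            x_pos += 1
        by_species: dict[str, list[str]] = {}
        for i in out_ids:
            by_species.setdefault(aln.species[i], []).append(aln.seqs[i][col])
        cons = outgroup_consensus(by_species, min_support=min_support)

        if cons is None or x is None or y is None:
            close("X")
            close("Y")
            continue

        # indel bookkeeping: gap in X or Y while the outgroups hold a residue
        for target, res in (("X", x), ("Y", y)):
            if res == GAP:
                if target not in runs:
                    pos = x_pos + 1 if target == "X" else x_pos
                    runs[target] = _IndelRun(target, col + 1, pos)
                runs[target].residues.append(cons)
            else:
                close(target)
        if x_gap or y == GAP:
            continue

        if x == cons and y == cons:
            continue
        pos = x_pos
        if x == y:  # derived in both haplotypes
            calls.append(
                ColumnCall(
                    column=col + 1,
                    position=pos,
                    category=SHARED_DERIVED,
                    outgroup_consensus=cons,
                    x_residue=x,
                    y_residue=y,
                    conservative=_is_conservative(matrix, cons, x, conservative_threshold),
                    notation=f"{cons}{pos}{x}",
                )
            )
            continue
        if x != cons:
            calls.append(
                ColumnCall(
                    column=col + 1,
                    position=pos,
                    category=X_SPECIFIC,
                    outgroup_consensus=cons,
                    x_residue=x,
                    y_residue=y,
                    conservative=_is_conservative(matrix, cons, x, conservative_threshold),
                    notation=f"{cons}{pos}{x}",
                )
            )
        if y != cons:
            calls.append(
                ColumnCall(
                    column=col + 1,
                    position=pos,
                    category=Y_SPECIFIC,
                    outgroup_consensus=cons,
                    x_residue=x,
                    y_residue=y,
                    conservative=_is_conservative(matrix, cons, y, conservative_threshold),
                    notation=f"{cons}{pos}{y}",
                )
            )
    close("X")
    close("Y")
    calls.sort(key=lambda c: (c.column, c.category))
    return calls


def table_report(calls: Iterable[ColumnCall], non_conserved_only: bool = False) -> dict[str, list[str]]:
    """Partition calls into the three report columns.

    Keys: ``shared`` (derived in both X and Y), ``x`` (X differs from
    the outgroups), ``y`` (Y differs).  INDEL events land in the column
    of the haplotype bearing the gap.  With ``non_conserved_only`` the
    report keeps only non-conservative substitutions (indels always
    kept), mirroring reports that list changes likely to disrupt the
    protein.
    """
    report: dict[str, list[str]] = {"shared": [], "x": [], "y": []}
    for call in calls:
        if non_conserved_only and call.category != INDEL and call.conservative:
            continue
        if call.category == SHARED_DERIVED:
            report["shared"].append(call.notation)
        elif call.category == X_SPECIFIC:
            report["x"].append(call.notation)
        elif call.category == Y_SPECIFIC:
            report["y"].append(call.notation)
        elif call.category == INDEL:
            key = "x" if call.indel_on == "X" else "y"
            report[key].extend(n.strip() for n in call.notation.split(","))
    return report
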