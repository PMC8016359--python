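"""Peptide-window segmentation around candidate lysine residues.

A candidate site is a lysine (K) in a protein sequence.  Each site is
represented by a fixed-length fragment of ``2*zeta + 1`` residues centred
on the K, with positions that fall off either end of the protein filled
with the dummy residue ``'X'``.  Nonstandard letters (B, J, O, U, Z, '*',
'-') are likewise folded into ``'X'`` so that every window lives on a
closed 21-letter alphabet: the 20 standard amino acids plus 'X'.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: Canonical alphabet order: the 20 standard residues alphabetically, then 'X'.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Letters folded into the dummy residue at parse/segmentation time.
NONSTANDARD = set("BJOUZ*-")

DEFAULT_ZETA = 14
MAX_ZETA = 32

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

_LABEL_ALIASES = {
    "positive": POSITIVE, "pos": POSITIVE, "1": POSITIVE, "true": POSITIVE,
    "negative": NEGATIVE, "neg": NEGATIVE, "0": NEGATIVE, "false": NEGATIVE,
}


class WindowingError(ValueError):
    """Raised for malformed sequence or site inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise WindowingError(f"protein {self.id!r}: empty sequence")
        if not self.sequence.isalpha():
            raise WindowingError(
                f"protein {self.id!r}: sequence contains non-letter characters"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A labelled candidate site: 1-based lysine position in a protein."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise WindowingError(
                f"site {self.protein_id}:{self.position}: position must be >= 1"
            )
        if self.label not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise WindowingError(
                f"site {self.protein_id}:{self.position}: bad label {self.label!r}"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """A lysine-centred fragment of length ``2*zeta + 1`` on the 21-letter alphabet."""

    protein_id: str
    position: int
    residues: str
    label: str = UNKNOWN

    @property
    def zeta(self) -> int:
        return (len(self.residues) - 1) // 2

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n < 3 or n % 2 == 0:
            raise WindowingError(
                f"window {self.protein_id}:{self.position}: length {n} is not 2*zeta+1"
            )
        if self.residues[n // 2] != "K":
            raise WindowingError(
                f"window {self.protein_id}:{self.position}: centre residue is "
                f"{self.residues[n // 2]!r}, expected 'K'"
            )
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise WindowingError(
                f"window {self.protein_id}:{self.position}: residues outside "
                f"alphabet: {sorted(bad)}"
            )


@dataclass
class WindowDataset:
    """An ordered collection of equal-length peptide windows."""

    windows: list[PeptideWindow]
    zeta: int

    def __post_init__(self) -> None:
        width = 2 * self.zeta + 1
        for w in self.windows:
            if len(w.residues) != width:
                raise WindowingError(
                    f"window {w.protein_id}:{w.position} has length "
                    f"{len(w.residues)}, dataset expects {width}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, label: str) -> list[PeptideWindow]:
        return [w for w in self.windows if w.label == label]

    @property
    def n_positive(self) -> int:
        return sum(1 for w in self.windows if w.label == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for w in self.windows if w.label == NEGATIVE)


def normalize_residues(sequence: str) -> str:
    """Uppercase and fold nonstandard letters into 'X'."""
    seq = sequence.upper()
    return "".join("X" if c in NONSTANDARD else c for c in seq)


def parse_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    The id is the header token before the first whitespace.  Sequences are
    uppercased; duplicate ids and empty files are rejected.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise WindowingError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise WindowingError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def parse_site_table(
    path: str | Path,
    proteins: Sequence[ProteinRecord] | None = None,
) -> list[SiteAnnotation]:
    """Read a TSV of ``protein_id  position  label`` rows.

    When *proteins* is given, each position is validated: it must fall
    inside the protein and the residue there (after nonstandard-letter
    folding) must be 'K'.
    """
    path = Path(path)
    by_id = {p.id: p for p in proteins} if proteins is not None else None
    annotations: list[SiteAnnotation] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise WindowingError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        if cols[:3] != ["protein_id", "position", "label"]:
            raise WindowingError(
                f"{path}: expected header 'protein_id\\tposition\\tlabel', got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise WindowingError(f"{path}:{lineno}: expected 3 columns")
            pid, pos_s, label_s = parts[0], parts[1], parts[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise WindowingError(
                    f"{path}:{lineno}: position {pos_s!r} is not an integer"
                ) from None
            label = _LABEL_ALIASES.get(label_s.strip().lower())
            if label is None:
                raise WindowingError(f"{path}:{lineno}: unknown label {label_s!r}")
            ann = SiteAnnotation(protein_id=pid, position=pos, label=label)
            if by_id is not None:
                _validate_site(ann, by_id, context=f"{path}:{lineno}")
            annotations.append(ann)
    return annotations


def write_site_table(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.position}\t{a.label}\n")


def _validate_site(
    ann: SiteAnnotation, by_id: dict[str, ProteinRecord], context: str = ""
) -> None:
    prefix = f"{context}: " if context else ""
    prot = by_id.get(ann.protein_id)
    if prot is None:
        raise WindowingError(f"{prefix}unknown protein {ann.protein_id!r}")
    if ann.position > len(prot):
        raise WindowingError(
            f"{prefix}site {ann.protein_id}:{ann.position} beyond protein "
            f"length {len(prot)}"
        )
    residue = normalize_residues(prot.sequence[ann.position - 1])
    if residue != "K":
        raise WindowingError(
            f"{prefix}site {ann.protein_id}:{ann.position}: residue "
            f"{residue!r} is not 'K'"
        )


def segment_window(
    protein: ProteinRecord, position: int, zeta: int = DEFAULT_ZETA
) -> PeptideWindow:
    """Cut the ``2*zeta + 1`` fragment centred on the K at *position* (1-based).

    Positions hanging over either terminus are filled with 'X', and any
    nonstandard residue inside the fragment is folded into 'X'.
    """
    if zeta < 1:
        raise WindowingError(f"zeta must be >= 1, got {zeta}")
    seq = normalize_residues(protein.sequence)
    if not (1 <= position <= len(seq)):
        raise WindowingError(
            f"{protein.id}: position {position} outside 1..{len(seq)}"
        )
    if seq[position - 1] != "K":
        raise WindowingError(
            f"{protein.id}: residue at {position} is {seq[position - 1]!r}, not 'K'"
        )
    i = position - 1
    left = seq[max(0, i - zeta) : i]
    right = seq[i + 1 : i + 1 + zeta]
    residues = "X" * (zeta - len(left)) + left + "K" + right + "X" * (zeta - len(right))
    return PeptideWindow(protein_id=protein.id, position=position, residues=residues)


def negative_sites_from_lysines(
    proteins: Sequence[ProteinRecord],
    positives: Sequence[SiteAnnotation],
) -> list[SiteAnnotation]:
    """Annotate every non-positive lysine as a negative site.

    This is the usual construction when a dataset lists only the modified
    sites: every other K in the same proteins is taken as unmodified.
    """
    positive_keys = {(a.protein_id, a.position) for a in positives}
    negatives: list[SiteAnnotation] = []
    for prot in proteins:
        seq = normalize_residues(prot.sequence)
        for i, res in enumerate(seq, start=1):
            if res == "K" and (prot.id, i) not in positive_keys:
                negatives.append(
                    SiteAnnotation(protein_id=prot.id, position=i, label=NEGATIVE)
                )
    return negatives


def build_dataset(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    zeta: int = DEFAULT_ZETA,
) -> WindowDataset:
    """Segment one window per annotation, ordered by (protein id, position)."""
    by_id = {p.id: p for p in proteins}
    if len(by_id) != len(proteins):
        dupes = sorted(
            {p.id for p in proteins if sum(q.id == p.id for q in proteins) > 1}
        )
        raise WindowingError(f"duplicate protein ids: {dupes}")
    missing = sorted({a.protein_id for a in annotations if a.protein_id not in by_id})
    if missing:
        raise WindowingError(f"annotations reference unknown proteins: {missing}")
    windows = []
    for ann in sorted(annotations, key=lambda a: (a.protein_id, a.position)):
        w = segment_window(by_id[ann.protein_id], ann.position, zeta)
        windows.append(
            PeptideWindow(
                protein_id=w.protein_id,
                position=w.position,
                residues=w.residues,
                label=ann.label,
            )
        )
    return WindowDataset(windows=windows, zeta=zeta)


def write_windows(dataset: WindowDataset, path: str | Path) -> None:
    """Export windows as TSV: ``protein_id  position  window  label``."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\twindow\tlabel\n")
        for w in dataset.windows:
            fh.write(f"{w.protein_id}\t{w.position}\t{w.residues}\t{w.label}\n")


def read_windows(path: str | Path) -> WindowDataset:
    """Load a window TSV written by :func:`write_windows`."""
    path = Path(path)
    windows: list[PeptideWindow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["protein_id", "position", "window", "label"]:
            raise WindowingError(f"{path}: bad window-file header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise WindowingError(f"{path}:{lineno}: expected 4 columns")
            windows.append(
                PeptideWindow(
                    protein_id=parts[0],
                    position=int(parts[1]),
                    residues=parts[2],
                    label=_LABEL_ALIASES.get(parts[3].lower(), parts[3]),
                )
            )
    if not windows:
        raise WindowingError(f"{path}: no windows")
    zeta = windows[0].zeta
    return WindowDataset(windows=windows, zeta=zeta)
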