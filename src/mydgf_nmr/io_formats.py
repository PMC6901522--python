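"""Readers and writers for the external formats the pipeline touches.

Covers Sparky-style assigned peak lists (one per experimental condition),
multi-model PDB coordinate ensembles, CYANA ``.upl``-style distance-restraint
tables, and two-column XY spectra (CD, fluorescence). Every reader has a
matching writer and the pair round-trips losslessly on valid input.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import gemmi
import numpy as np

__all__ = [
    "AssignmentLabel",
    "Peak",
    "Condition",
    "PeakList",
    "AtomRecord",
    "StructureEnsemble",
    "RestraintRecord",
    "XYSpectrum",
    "ParseError",
    "parse_assignment_label",
    "read_peaklist",
    "write_peaklist",
    "read_ensemble",
    "write_ensemble",
    "read_restraint_table",
    "write_restraint_table",
    "read_xy_table",
    "write_xy_table",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# --------------------------------------------------------------------------
# assignment labels
# --------------------------------------------------------------------------

_LABEL_RE = re.compile(
    r"^(?P<rtype>[A-Z])(?P<rnum>\d+)(?P<atom1>[A-Za-z][A-Za-z0-9']*)-(?P<atom2>[A-Za-z][A-Za-z0-9']*)$"
)


@dataclass(frozen=True, order=True)
class AssignmentLabel:
    """An assigned resonance label such as ``H49N-H``.

    ``residue_type`` is the one-letter amino-acid code, ``residue_number``
    the sequence position, and ``atoms`` the ordered pair of atom names
    (``("N", "H")`` for a backbone amide).
    """

    residue_type: str
    residue_number: int
    atoms: tuple[str, str] = ("N", "H")

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue number must be >= 1, got {self.residue_number}")
        if not all(self.atoms):
            raise ValueError("atom names must be non-empty")

    @property
    def residue_key(self) -> str:
        return f"{self.residue_type}{self.residue_number}"

    def render(self) -> str:
        return f"{self.residue_type}{self.residue_number}{self.atoms[0]}-{self.atoms[1]}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_assignment_label(text: str) -> AssignmentLabel:
    """Parse a Sparky-dialect assignment label (e.g. ``"H49N-H"``).

    The format is one-letter residue type, residue number, then the two atom
    names joined by ``-``. ``render`` of the result reproduces the input.
    """
    if not text:
        raise ParseError("empty assignment label")
    m = _LABEL_RE.match(text.strip())
    if m is None:
        raise ParseError(f"malformed assignment label: {text!r}")
    return AssignmentLabel(
        residue_type=m.group("rtype"),
        residue_number=int(m.group("rnum")),
        atoms=(m.group("atom1"), m.group("atom2")),
    )


# --------------------------------------------------------------------------
# peaks and peak lists
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """One assigned HSQC cross-peak: label plus (delta_N, delta_H) in ppm.

    ``delta_N`` is the 15N (w1, indirect) shift and ``delta_H`` the 1H (w2)
    shift; the two dimensions are never interchangeable.
    """

    label: AssignmentLabel
    delta_N: float
    delta_H: float
    height: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_N) and np.isfinite(self.delta_H)):
            raise ValueError(f"non-finite chemical shift for {self.label}")

    def shifted(self, d_h: float, d_n: float) -> "Peak":
        """Return a copy displaced by (d_h ppm in 1H, d_n ppm in 15N)."""
        return Peak(self.label, self.delta_N + d_n, self.delta_H + d_h, self.height)


@dataclass(frozen=True)
class Condition:
    """Experimental condition metadata attached to one spectrum."""

    name: str
    pH: float | None = None
    ligand_conc: float | None = None
    ligand_unit: str = ""

    def __post_init__(self) -> None:
        if self.pH is not None and not (0.0 < self.pH < 14.0):
            raise ValueError(f"pH out of range (0, 14): {self.pH}")


class PeakList:
    """Assigned peaks of one spectrum, keyed by :class:`AssignmentLabel`."""

    def __init__(self, condition: Condition, peaks: Iterable[Peak]):
        self.condition = condition
        self._peaks: dict[AssignmentLabel, Peak] = {}
        for p in peaks:
            if p.label in self._peaks:
                raise ParseError(f"duplicate peak label {p.label.render()}")
            self._peaks[p.label] = p
        if not self._peaks:
            raise ParseError(f"empty peak list for condition {condition.name!r}")

    def __len__(self) -> int:
        return len(self._peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self._peaks.values())

    def __contains__(self, label: AssignmentLabel) -> bool:
        return label in self._peaks

    def __getitem__(self, label: AssignmentLabel) -> Peak:
        return self._peaks[label]

    def get(self, label: AssignmentLabel) -> Peak | None:
        return self._peaks.get(label)

    @property
    def labels(self) -> set[AssignmentLabel]:
        return set(self._peaks)

    def common_labels(self, other: "PeakList") -> set[AssignmentLabel]:
        return self.labels & other.labels

    def shifted(self, d_h: float, d_n: float) -> "PeakList":
        return PeakList(self.condition, (p.shifted(d_h, d_n) for p in self))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakList):
            return NotImplemented
        return self.condition == other.condition and self._peaks == other._peaks


def read_peaklist(source: TextIO | str, condition: Condition) -> PeakList:
    """Read a Sparky-style peak list.

    Whitespace-delimited columns: label, w1 (15N ppm), w2 (1H ppm), and an
    optional height. A header line (first token not a valid label), blank
    lines and ``#`` comments are tolerated. Duplicate labels and non-numeric
    shifts are errors.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    peaks: list[Peak] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if _LABEL_RE.match(tokens[0]) is None:
            # header line ("Assignment w1 w2 ...") — skip, but only before data
            if not peaks:
                continue
            raise ParseError(f"line {lineno}: malformed label {tokens[0]!r}")
        if len(tokens) < 3:
            raise ParseError(f"line {lineno}: expected label w1 w2 [height]")
        label = parse_assignment_label(tokens[0])
        try:
            w1 = float(tokens[1])
            w2 = float(tokens[2])
            height = float(tokens[3]) if len(tokens) > 3 else None
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
        peaks.append(Peak(label, delta_N=w1, delta_H=w2, height=height))
    return PeakList(condition, peaks)


def write_peaklist(peaklist: PeakList, dest: TextIO) -> None:
    """Write a peak list in the column order :func:`read_peaklist` expects."""
    has_height = any(p.height is not None for p in peaklist)
    header = "Assignment w1 w2" + (" Height" if has_height else "")
    dest.write(header + "\n")
    for p in sorted(peaklist, key=lambda p: p.label):
        # repr keeps the round trip lossless
        row = f"{p.label.render()} {float(p.delta_N)!r} {float(p.delta_H)!r}"
        if has_height:
            row += f" {float(p.height)!r}" if p.height is not None else " 0"
        dest.write(row + "\n")


# --------------------------------------------------------------------------
# coordinate ensembles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom, constant across the models of an ensemble."""

    chain: str
    residue_number: int
    residue_type: str
    atom_name: str
    element: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.atom_name)


class StructureEnsemble:
    """A multi-model coordinate set with identical atom composition per model.

    ``coords`` has shape ``(n_models, n_atoms, 3)`` in Å; ``atoms`` carries
    the per-atom identity shared by all models. Model 1 (index 0) is treated
    downstream as the lowest-energy conformer.
    """

    def __init__(self, atoms: Sequence[AtomRecord], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one model")
        if coords.shape[1] != len(atoms):
            raise ValueError("coords second axis must match number of atoms")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        self.atoms = list(atoms)
        self.coords = coords

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_mask(
        self,
        residues: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Boolean mask over atoms by residue number / atom name / heavy."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            rset = set(residues)
            mask &= np.array([a.residue_number in rset for a in self.atoms])
        if atom_names is not None:
            aset = set(atom_names)
            mask &= np.array([a.atom_name in aset for a in self.atoms])
        if heavy_only:
            mask &= np.array([not _is_hydrogen(a) for a in self.atoms])
        return mask


def _is_hydrogen(atom: AtomRecord) -> bool:
    if atom.element:
        return atom.element.upper() == "H"
    name = atom.atom_name.lstrip("0123456789")
    return name[:1].upper() in ("H", "D")


def read_ensemble(source: str | TextIO) -> StructureEnsemble:
    """Parse a (multi-MODEL) PDB file into a :class:`StructureEnsemble`.

    A file without MODEL records yields a one-model ensemble. Models with
    mismatched atom composition are rejected, naming the first discrepancy.
    Altloc codes other than blank or 'A' are rejected (NMR ensembles do not
    carry alternate locations).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:  # type: ignore[arg-type]
                text = fh.read()
        except (OSError, ValueError):
            text = source  # raw PDB text
    structure = gemmi.read_pdb_string(text)
    if len(structure) == 0:
        raise ParseError("no models found in PDB input")

    ref_atoms: list[AtomRecord] | None = None
    model_coords: list[np.ndarray] = []
    for model in structure:
        atoms: list[AtomRecord] = []
        xyz: list[tuple[float, float, float]] = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("\0", "", "A"):
                        raise ParseError(
                            f"unsupported altloc {atom.altloc!r} on "
                            f"{chain.name}/{residue.seqid.num}/{atom.name}"
                        )
                    atoms.append(
                        AtomRecord(
                            chain=chain.name,
                            residue_number=residue.seqid.num,
                            residue_type=residue.name,
                            atom_name=atom.name,
                            element=atom.element.name,
                        )
                    )
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        if ref_atoms is None:
            ref_atoms = atoms
        elif [a.key for a in atoms] != [a.key for a in ref_atoms]:
            bad = next(
                (i for i, (a, b) in enumerate(zip(atoms, ref_atoms)) if a.key != b.key),
                min(len(atoms), len(ref_atoms)),
            )
            raise ParseError(
                f"model {len(model_coords) + 1} atom composition differs from model 1 "
                f"at atom index {bad}"
            )
        model_coords.append(np.asarray(xyz, dtype=float))
    assert ref_atoms is not None
    return StructureEnsemble(ref_atoms, np.stack(model_coords))


def write_ensemble(
    ensemble: StructureEnsemble,
    dest: TextIO,
    b_factors: Mapping[int, float] | None = None,
    default_b: float = 0.0,
) -> None:
    """Write an ensemble as multi-MODEL PDB text.

    ``b_factors`` optionally maps residue number -> B-factor, applied to all
    atoms of that residue in every model (used to paint per-residue bins).
    """
    serial_fmt = (
        "ATOM  {serial:>5} {name:<4}{resname:>4} {chain:>1}{resnum:>4}    "
        "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2}\n"
    )
    for m in range(ensemble.n_models):
        dest.write(f"MODEL     {m + 1:>4}\n")
        for i, atom in enumerate(ensemble.atoms):
            x, y, z = ensemble.coords[m, i]
            b = default_b
            if b_factors is not None:
                b = b_factors.get(atom.residue_number, default_b)
            name = atom.atom_name if len(atom.atom_name) >= 4 else f" {atom.atom_name:<3}"
            dest.write(
                serial_fmt.format(
                    serial=i + 1,
                    name=name,
                    resname=atom.residue_type,
                    chain=atom.chain[:1] or "A",
                    resnum=atom.residue_number,
                    x=x,
                    y=y,
                    z=z,
                    occ=1.0,
                    b=b,
                    elem=atom.element,
                )
            )
        dest.write("ENDMDL\n")
    dest.write("END\n")


# --------------------------------------------------------------------------
# distance restraints
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RestraintRecord:
    """An NOE upper-bound distance restraint between two assigned atoms."""

    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    upper_bound: float
    resname_i: str = ""
    resname_j: str = ""

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValueError(f"non-positive restraint bound {self.upper_bound}")
        if self.res_i < 1 or self.res_j < 1:
            raise ValueError("restraint residue numbers must be >= 1")

    @property
    def sequence_separation(self) -> int:
        return abs(self.res_i - self.res_j)


def read_restraint_table(
    source: TextIO | str, dialect: str = "cyana-upl"
) -> list[RestraintRecord]:
    """Read a distance-restraint table.

    ``cyana-upl``: res_i resname_i atom_i res_j resname_j atom_j bound.
    ``tabular``:   res_i atom_i res_j atom_j bound.
    Comment (``#``) and blank lines are skipped; every data line yields one
    record (ambiguous or duplicated entries are preserved as-is).
    """
    if dialect not in ("cyana-upl", "tabular"):
        raise ValueError(f"unknown restraint dialect {dialect!r}")
    if isinstance(source, str):
        source = io.StringIO(source)
    records: list[RestraintRecord] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        t = line.split()
        try:
            if dialect == "cyana-upl":
                if len(t) < 7:
                    raise ValueError("expected 7 columns")
                rec = RestraintRecord(
                    res_i=int(t[0]),
                    resname_i=t[1],
                    atom_i=t[2],
                    res_j=int(t[3]),
                    resname_j=t[4],
                    atom_j=t[5],
                    upper_bound=float(t[6]),
                )
            else:
                if len(t) < 5:
                    raise ValueError("expected 5 columns")
                rec = RestraintRecord(
                    res_i=int(t[0]),
                    atom_i=t[1],
                    res_j=int(t[2]),
                    atom_j=t[3],
                    upper_bound=float(t[4]),
                )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


def write_restraint_table(
    records: Sequence[RestraintRecord], dest: TextIO, dialect: str = "cyana-upl"
) -> None:
    for r in records:
        if dialect == "cyana-upl":
            dest.write(
                f"{r.res_i:>4} {r.resname_i or 'XXX':<4} {r.atom_i:<5} "
                f"{r.res_j:>4} {r.resname_j or 'XXX':<4} {r.atom_j:<5} "
                f"{r.upper_bound:.2f}\n"
            )
        elif dialect == "tabular":
            dest.write(f"{r.res_i} {r.atom_i} {r.res_j} {r.atom_j} {r.upper_bound:.2f}\n")
        else:
            raise ValueError(f"unknown restraint dialect {dialect!r}")


# --------------------------------------------------------------------------
# two-column XY spectra
# --------------------------------------------------------------------------


@dataclass
class XYSpectrum:
    """A sampled 1D spectrum: strictly increasing x (nm) vs signal y."""

    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 3:
            raise ValueError("spectrum needs at least 3 points")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x grid must be strictly increasing (no duplicates)")

    def __len__(self) -> int:
        return len(self.x)


def read_xy_table(source: TextIO | str, **meta) -> XYSpectrum:
    """Read a two-column numeric table with comma/tab/whitespace delimiters.

    Rows are sorted ascending in x (pairs kept intact); duplicated x values
    are an error. Caller-supplied ``meta`` (units, condition) is attached.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        for delim in (",", "\t", None):
            tokens = line.split(delim)
            tokens = [t for t in tokens if t.strip()]
            if len(tokens) >= 2:
                try:
                    xv, yv = float(tokens[0]), float(tokens[1])
                    break
                except ValueError:
                    continue
        else:
            raise ParseError(f"line {lineno}: could not parse two numeric columns")
        xs.append(xv)
        ys.append(yv)
    if len(xs) < 3:
        raise ParseError("spectrum needs at least 3 data rows")
    order = np.argsort(np.asarray(xs), kind="stable")
    x = np.asarray(xs)[order]
    y = np.asarray(ys)[order]
    if np.any(np.diff(x) == 0):
        raise ParseError("duplicated x values in spectrum")
    return XYSpectrum(x, y, dict(meta))


def write_xy_table(spec: XYSpectrum, dest: TextIO, delimiter: str = ",") -> None:
    for xv, yv in zip(spec.x, spec.y):
        dest.write(f"{float(xv)!r}{delimiter}{float(yv)!r}\n")
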