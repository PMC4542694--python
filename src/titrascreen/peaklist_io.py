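"""Reading and writing of 2D amide peak lists.

One :class:`PeakList` holds all picked cross-peaks of a single
:sup:`1`\\ H-:sup:`15`\\ N correlation spectrum at one pH.  Three dialects are
supported:

* **csv** — the canonical interchange format of this package, header
  ``subunit,residue_number,residue_type,delta_h_ppm,delta_n_ppm,intensity``
  with the condition pH carried in a ``# pH=<value>`` comment line;
* **sparky** — Sparky-like ``<assignment> <w1(15N)> <w2(1H)> [height]``
  columns (note the 15N axis first, the Sparky w1/w2 convention);
* **nmrstar** — a minimal reader for the ``Atom_chem_shift`` loop of an
  NMR-STAR file (amide H/N pairs only).

All readers normalise into the same in-memory model, so every downstream
stage sees one representation regardless of the source dialect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Assignment",
    "Peak",
    "PeakList",
    "PeakListError",
    "read_peaklist",
    "write_peaklist",
]

# amide chemical-shift sanity windows (ppm); outside -> warning, not error
H_WINDOW = (5.0, 12.0)
N_WINDOW = (100.0, 135.0)

#: default per-subunit residue-count bounds (acidic subunit NAS, basic NBS)
DEFAULT_SUBUNIT_BOUNDS = {"NAS": 113, "NBS": 114}


class PeakListError(ValueError):
    """Malformed peak-list content (bad row, duplicate assignment, ...)."""


@dataclass(frozen=True, order=True)
class Assignment:
    """Backbone amide assignment: subunit label + residue number + type."""

    subunit: str
    residue_number: int
    residue_type: str = "X"

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise PeakListError(
                f"residue_number must be >= 1, got {self.residue_number}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.subunit, self.residue_number)

    def label(self) -> str:
        return f"{self.subunit} {self.residue_type}{self.residue_number}"


@dataclass
class Peak:
    """One amide cross-peak: (δH, δN) in ppm, optional intensity/assignment."""

    peak_id: str
    delta_h: float
    delta_n: float
    intensity: Optional[float] = None
    assignment: Optional[Assignment] = None

    def validate(self) -> None:
        for name, value in (("delta_h", self.delta_h), ("delta_n", self.delta_n)):
            if not _finite(value):
                raise PeakListError(f"peak {self.peak_id}: {name} is not numeric")
        if not (H_WINDOW[0] <= self.delta_h <= H_WINDOW[1]):
            warnings.warn(
                f"peak {self.peak_id}: delta_h={self.delta_h:.3f} ppm outside "
                f"amide window {H_WINDOW}",
                stacklevel=2,
            )
        if not (N_WINDOW[0] <= self.delta_n <= N_WINDOW[1]):
            warnings.warn(
                f"peak {self.peak_id}: delta_n={self.delta_n:.3f} ppm outside "
                f"amide window {N_WINDOW}",
                stacklevel=2,
            )


@dataclass
class PeakList:
    """All peaks of one spectrum recorded at one pH."""

    condition_ph: float
    peaks: list[Peak] = field(default_factory=list)
    temperature: Optional[float] = None
    field_mhz: Optional[float] = None
    subunit_bounds: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBUNIT_BOUNDS)
    )

    def validate(self) -> None:
        if not (0.0 <= self.condition_ph <= 14.0):
            raise PeakListError(f"condition_ph {self.condition_ph} outside [0, 14]")
        seen_ids: set[str] = set()
        seen_assign: set[tuple[str, int]] = set()
        for pk in self.peaks:
            pk.validate()
            a = pk.assignment
            if a is not None and a.key in seen_assign:
                raise PeakListError(
                    f"duplicate assignment {a.subunit} {a.residue_number}"
                )
            if pk.peak_id in seen_ids:
                raise PeakListError(f"duplicate peak_id {pk.peak_id!r}")
            seen_ids.add(pk.peak_id)
            if a is None:
                continue
            bound = self.subunit_bounds.get(a.subunit)
            if bound is not None and a.residue_number > bound:
                raise PeakListError(
                    f"{a.subunit} residue {a.residue_number} exceeds subunit "
                    f"length {bound}"
                )
            seen_assign.add(a.key)

    def assigned(self) -> dict[tuple[str, int], Peak]:
        return {p.assignment.key: p for p in self.peaks if p.assignment is not None}

    def __len__(self) -> int:
        return len(self.peaks)


def _finite(x) -> bool:
    try:
        return float(x) == float(x) and abs(float(x)) != float("inf")
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

CSV_HEADER = "subunit,residue_number,residue_type,delta_h_ppm,delta_n_ppm,intensity"

_PH_RE = re.compile(r"#\s*pH\s*=\s*([0-9.+-eE]+)")


def _read_csv(path: Path) -> PeakList:
    ph: Optional[float] = None
    peaks: list[Peak] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _PH_RE.search(line)
                if m:
                    ph = float(m.group(1))
                continue
            if not header_seen:
                if line.replace(" ", "") != CSV_HEADER:
                    raise PeakListError(
                        f"{path}:{lineno}: expected header {CSV_HEADER!r}, "
                        f"got {line!r}"
                    )
                header_seen = True
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) not in (5, 6):
                raise PeakListError(
                    f"{path}:{lineno}: expected 5-6 comma-separated fields, "
                    f"got {len(fields)}"
                )
            sub, resnum, restype, dh, dn = fields[:5]
            inten = fields[5] if len(fields) == 6 and fields[5] != "" else None
            try:
                delta_h, delta_n = float(dh), float(dn)
                intensity = float(inten) if inten is not None else None
            except ValueError as exc:
                raise PeakListError(f"{path}:{lineno}: non-numeric field: {exc}")
            if sub:
                try:
                    assignment = Assignment(sub, int(resnum), restype or "X")
                except ValueError:
                    raise PeakListError(
                        f"{path}:{lineno}: bad residue number {resnum!r}"
                    )
                pid = f"{sub}{resnum}"
            else:
                assignment = None
                pid = f"pk{lineno}"
            peaks.append(Peak(pid, delta_h, delta_n, intensity, assignment))
    if ph is None:
        raise PeakListError(f"{path}: missing '# pH=<value>' header line")
    return PeakList(condition_ph=ph, peaks=peaks)


def _write_csv(plist: PeakList, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pH={plist.condition_ph:g}\n")
        if plist.temperature is not None:
            fh.write(f"# temperature_c={plist.temperature:g}\n")
        if plist.field_mhz is not None:
            fh.write(f"# field_mhz={plist.field_mhz:g}\n")
        fh.write(CSV_HEADER + "\n")
        for pk in plist.peaks:
            a = pk.assignment
            sub = a.subunit if a else ""
            num = str(a.residue_number) if a else ""
            typ = a.residue_type if a else ""
            inten = f"{pk.intensity:.6g}" if pk.intensity is not None else ""
            fh.write(f"{sub},{num},{typ},{pk.delta_h:.4f},{pk.delta_n:.4f},{inten}\n")


# ---------------------------------------------------------------------------
# Sparky-like dialect
# ---------------------------------------------------------------------------

# e.g. "H11N-H", "NBS:H11N-H", "T9N-H"; "?-?" for unassigned
_SPARKY_LABEL_RE = re.compile(
    r"^(?:(?P<sub>[A-Za-z0-9]+):)?(?P<type>[A-Z])(?P<num>\d+)N-H$"
)


def _read_sparky(path: Path, default_subunit: Optional[str] = None) -> PeakList:
    ph: Optional[float] = None
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _PH_RE.search(line)
                if m:
                    ph = float(m.group(1))
                continue
            if line.lower().startswith("assignment"):
                continue  # Sparky column header
            fields = line.split()
            if len(fields) not in (3, 4):
                raise PeakListError(
                    f"{path}:{lineno}: expected 3-4 whitespace fields, "
                    f"got {len(fields)}"
                )
            label, w1, w2 = fields[:3]
            try:
                delta_n, delta_h = float(w1), float(w2)  # w1 = 15N, w2 = 1H
                intensity = float(fields[3]) if len(fields) == 4 else None
            except ValueError as exc:
                raise PeakListError(f"{path}:{lineno}: non-numeric field: {exc}")
            assignment = None
            if label not in ("?-?", "?"):
                m = _SPARKY_LABEL_RE.match(label)
                if m is None:
                    raise PeakListError(
                        f"{path}:{lineno}: unparseable Sparky label {label!r}"
                    )
                sub = m.group("sub") or default_subunit
                if sub is None:
                    raise PeakListError(
                        f"{path}:{lineno}: label {label!r} carries no subunit and "
                        "no default_subunit was given"
                    )
                assignment = Assignment(sub, int(m.group("num")), m.group("type"))
                pid = f"{sub}{m.group('num')}"
            else:
                pid = f"pk{lineno}"
            peaks.append(Peak(pid, delta_h, delta_n, intensity, assignment))
    if ph is None:
        raise PeakListError(f"{path}: missing '# pH=<value>' header line")
    return PeakList(condition_ph=ph, peaks=peaks)


def _write_sparky(plist: PeakList, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pH={plist.condition_ph:g}\n")
        fh.write(f"{'Assignment':>16} {'w1':>10} {'w2':>10} {'Height':>12}\n")
        for pk in plist.peaks:
            a = pk.assignment
            label = f"{a.subunit}:{a.residue_type}{a.residue_number}N-H" if a else "?-?"
            inten = f"{pk.intensity:12.6g}" if pk.intensity is not None else ""
            fh.write(f"{label:>16} {pk.delta_n:10.4f} {pk.delta_h:10.4f} {inten}\n")


# ---------------------------------------------------------------------------
# minimal NMR-STAR Atom_chem_shift loop
# ---------------------------------------------------------------------------

def _read_nmrstar(path: Path, ph: Optional[float] = None) -> PeakList:
    """Read amide H/N shifts from the Atom_chem_shift loop of an NMR-STAR file.

    Only the chemical-shift loop is interpreted; entity assembly IDs are
    mapped to subunit labels via ``_Atom_chem_shift.Entity_assembly_ID``
    order (1 -> NAS, 2 -> NBS) unless ``Auth_asym_ID``-style labels are
    already strings.  The condition pH may be supplied by a ``# pH=`` comment
    (a dialect convention of this package) or the ``ph`` argument.
    """
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    collecting_tags = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                m = _PH_RE.search(line)
                if m:
                    ph = float(m.group(1))
                continue
            if line == "loop_":
                in_loop, collecting_tags = True, True
                tags, rows = [], []
                continue
            if not in_loop:
                continue
            if line.startswith("_"):
                if collecting_tags:
                    tags.append(line.split()[0])
                continue
            collecting_tags = False
            if line in ("stop_", ""):
                if line == "stop_":
                    if any(t.startswith("_Atom_chem_shift.") for t in tags):
                        break  # found and finished the shift loop
                    in_loop = False
                continue
            rows.append(line.split())

    if not any(t.startswith("_Atom_chem_shift.") for t in tags):
        raise PeakListError(f"{path}: no _Atom_chem_shift loop found")

    def col(name: str) -> int:
        full = f"_Atom_chem_shift.{name}"
        if full not in tags:
            raise PeakListError(f"{path}: missing tag {full}")
        return tags.index(full)

    i_ent = col("Entity_assembly_ID")
    i_seq = col("Comp_index_ID")
    i_comp = col("Comp_ID")
    i_atom = col("Atom_ID")
    i_val = col("Val")

    entity_map = {"1": "NAS", "2": "NBS"}
    shifts: dict[tuple[str, int], dict[str, float]] = {}
    types: dict[tuple[str, int], str] = {}
    for row in rows:
        if len(row) <= max(i_ent, i_seq, i_comp, i_atom, i_val):
            raise PeakListError(f"{path}: short Atom_chem_shift row: {row}")
        atom = row[i_atom]
        if atom not in ("H", "N"):
            continue
        ent = row[i_ent]
        sub = entity_map.get(ent, ent)
        key = (sub, int(row[i_seq]))
        shifts.setdefault(key, {})[atom] = float(row[i_val])
        types[key] = _three_to_one(row[i_comp])

    peaks = []
    for (sub, num), hn in sorted(shifts.items()):
        if "H" not in hn or "N" not in hn:
            continue
        peaks.append(
            Peak(
                f"{sub}{num}",
                hn["H"],
                hn["N"],
                None,
                Assignment(sub, num, types[(sub, num)]),
            )
        )
    if ph is None:
        raise PeakListError(f"{path}: condition pH not given (argument or '# pH=')")
    return PeakList(condition_ph=ph, peaks=peaks)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def _three_to_one(comp: str) -> str:
    return _THREE_TO_ONE.get(comp.upper(), "X")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_peaklist(
    path,
    format: str = "csv",
    *,
    ph: Optional[float] = None,
    default_subunit: Optional[str] = None,
) -> PeakList:
    """Read one peak list and return a validated :class:`PeakList`.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``csv``, ``sparky``, ``nmrstar``.
    ph
        Condition pH override (required for NMR-STAR files without a
        ``# pH=`` comment).
    default_subunit
        Subunit assumed for Sparky labels without an explicit
        ``<subunit>:`` prefix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        plist = _read_csv(path)
    elif format == "sparky":
        plist = _read_sparky(path, default_subunit=default_subunit)
    elif format == "nmrstar":
        plist = _read_nmrstar(path, ph=ph)
    else:
        raise ValueError(f"unknown peak-list format {format!r}")
    if ph is not None:
        plist = replace(plist, condition_ph=ph)
    plist.validate()
    return plist


def write_peaklist(plist: PeakList, path, format: str = "csv") -> None:
    """Serialize a :class:`PeakList`; ppm values keep >= 4 decimals."""
    plist.validate()
    path = Path(path)
    if format == "csv":
        _write_csv(plist, path)
    elif format == "sparky":
        _write_sparky(plist, path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


def read_series(paths: Iterable, format: str = "csv", **kwargs) -> list[PeakList]:
    """Read several peak lists and order them by ascending pH."""
    lists = [read_peaklist(p, format=format, **kwargs) for p in paths]
    lists.sort(key=lambda pl: pl.condition_ph)
    return lists
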