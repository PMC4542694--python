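"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is deterministic given (scenario, seed) and returns its
ground truth alongside the data, so pipeline-vs-truth comparisons are fully
automated:

* :func:`generate_titration` — per-pH amide peak lists whose shifts follow a
  single-site Henderson–Hasselbalch titration, with Gaussian ppm noise and
  optional exchange-broadened (omitted) peaks;
* :func:`generate_structure` / :func:`random_structure` — two-chain toy
  structures with analytically known inter-residue distances, writable as
  PDB;
* :func:`generate_assay` — Hill-curve cell responses with binomial counting
  noise (the assay counts responding cells);
* :func:`generate_saxs` — sphere-form-factor scattering profiles.

The ``reference_*`` scenario builders emulate the shape of a two-subunit
heterodimeric titration screen: an acidic subunit (NAS, 113 residues) and a
basic subunit (NBS, 114 residues), 36 + 33 residues with significant shift
changes between pH 3 and 7, and 2 + 10 residues whose peaks vanish above
pH 4 from intermediate-timescale conformational exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import gemmi

from .peaklist_io import Assignment, Peak, PeakList, _ONE_TO_THREE
from .titration import ScreenConfig
from .structure_map import Residue3D, StructureModel
from .doseresponse import ResponseTable, hill_curve

__all__ = [
    "ResidueSpec",
    "TitrationScenario",
    "generate_titration",
    "uniform_titration_scenario",
    "reference_screen_scenario",
    "hh_theta",
    "analytic_f_low",
    "analytic_group",
    "generate_structure",
    "random_structure",
    "write_structure_pdb",
    "reference_screen_structure",
    "VariantSpec",
    "AssayScenario",
    "generate_assay",
    "reference_assay_scenario",
    "generate_saxs",
    "sphere_intensity",
    "sphere_rg",
]

DEFAULT_SEED = 20150811


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

def hh_theta(ph, pka: float, n: float = 1.0):
    """Protonated fraction θ(pH) = 1 / (1 + 10^{n(pH − pKa)})."""
    return 1.0 / (1.0 + 10.0 ** (n * (np.asarray(ph, dtype=float) - pka)))


@dataclass(frozen=True)
class ResidueSpec:
    """Ground-truth trajectory of one residue.

    ``pka=None`` makes the residue static at its base position.  The base
    endpoint (δ at full deprotonation) sits at (h_base, n_base); the acidic
    endpoint is displaced by (dh_amp, dn_amp) ppm.  ``missing_phs`` lists pH
    values where the peak is exchange-broadened out of the spectrum.
    """

    subunit: str
    residue_number: int
    residue_type: str = "X"
    pka: Optional[float] = None
    hill_n: float = 1.0
    h_base: float = 8.2
    n_base: float = 118.0
    dh_amp: float = 0.0
    dn_amp: float = 0.0
    missing_phs: frozenset[float] = frozenset()

    def shifts_at(self, ph) -> tuple[np.ndarray, np.ndarray]:
        """Noiseless (δH, δN) at the given pH values."""
        ph = np.asarray(ph, dtype=float)
        if self.pka is None:
            theta = np.zeros_like(ph)
        else:
            theta = hh_theta(ph, self.pka, self.hill_n)
        return self.h_base + self.dh_amp * theta, self.n_base + self.dn_amp * theta


@dataclass(frozen=True)
class TitrationScenario:
    residues: tuple[ResidueSpec, ...]
    ph_grid: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0, 7.0)
    sigma_h: float = 0.0
    sigma_n: float = 0.0
    seed: int = DEFAULT_SEED


def analytic_f_low(
    pka: Optional[float],
    config: ScreenConfig = ScreenConfig(),
    ph_grid: Sequence[float] = (3.0, 4.0, 5.0, 6.0, 7.0),
    hill_n: float = 1.0,
) -> Optional[float]:
    """Closed-form path-length fraction below ph_mid for an HH trajectory.

    Every channel of a single-site trajectory is proportional to θ(pH), so
    segment path lengths are proportional to |Δθ| and the fraction reduces
    to sums of θ differences over the grid — no peak lists involved.  This
    is the independent oracle for the pipeline classifier.
    """
    if pka is None:
        return None
    grid = sorted(p for p in ph_grid if config.ph_lo <= p <= config.ph_hi)
    theta = hh_theta(np.array(grid), pka, hill_n)
    low = 0.0
    total = 0.0
    for (p1, t1), (p2, t2) in zip(zip(grid, theta), zip(grid[1:], theta[1:])):
        seg = abs(t2 - t1)
        total += seg
        if p2 <= config.ph_mid:
            low += seg
        elif p1 < config.ph_mid < p2:
            low += seg * (config.ph_mid - p1) / (p2 - p1)
    return None if total == 0 else low / total


def analytic_group(
    spec: ResidueSpec,
    config: ScreenConfig = ScreenConfig(),
    ph_grid: Sequence[float] = (3.0, 4.0, 5.0, 6.0, 7.0),
) -> str:
    """Ground-truth group label from the closed form (same decision rule)."""
    if spec.missing_phs & {config.ph_lo, config.ph_hi}:
        return "none"
    h, n = spec.shifts_at([config.ph_lo, config.ph_hi])
    dh, dn = abs(h[1] - h[0]), abs(n[1] - n[0])
    significant = dh > config.h_threshold or dn > config.n_threshold
    if not significant:
        return "none"
    f_low = analytic_f_low(spec.pka, config, ph_grid, spec.hill_n)
    if f_low is None:
        return "none"
    return "A" if f_low > config.f_low_cut else "B"


def generate_titration(
    scenario: TitrationScenario, config: ScreenConfig = ScreenConfig()
) -> tuple[list[PeakList], pd.DataFrame]:
    """Per-pH peak lists plus a ground-truth table.

    The truth table carries, per residue: true pKa, endpoint shift
    differences, the significance call, the closed-form ``f_low`` and group
    label, and the exchange-broadened pH set — all computed from the
    noiseless model, never through the pipeline under test.
    """
    rng = np.random.default_rng(scenario.seed)
    phs = sorted(scenario.ph_grid)
    if len(set(phs)) != len(phs):
        raise ValueError("duplicate pH values in grid")

    lists = []
    for ph in phs:
        peaks = []
        for spec in scenario.residues:
            if ph in spec.missing_phs:
                continue
            h, n = spec.shifts_at(ph)
            dh = float(h) + rng.normal(0.0, scenario.sigma_h)
            dn = float(n) + rng.normal(0.0, scenario.sigma_n)
            # only the lowest pH is assigned: downstream tracking must
            # recover the rest, as in an extrapolation-based assignment
            assignment = (
                Assignment(spec.subunit, spec.residue_number, spec.residue_type)
                if ph == phs[0]
                else None
            )
            pid = f"{spec.subunit}{spec.residue_number}"
            peaks.append(Peak(pid, dh, dn, None, assignment))
        lists.append(PeakList(condition_ph=ph, peaks=peaks))

    rows = []
    for spec in scenario.residues:
        h, n = spec.shifts_at([config.ph_lo, config.ph_hi])
        dh_tot, dn_tot = abs(h[1] - h[0]), abs(n[1] - n[0])
        evaluable = not (spec.missing_phs & {config.ph_lo, config.ph_hi})
        significant = evaluable and (
            dh_tot > config.h_threshold or dn_tot > config.n_threshold
        )
        rows.append(
            {
                "subunit": spec.subunit,
                "residue": spec.residue_number,
                "residue_type": spec.residue_type,
                "pka_true": spec.pka,
                "dH_true": dh_tot if evaluable else np.nan,
                "dN_true": dn_tot if evaluable else np.nan,
                "significant_true": significant,
                "f_low_true": analytic_f_low(spec.pka, config, phs, spec.hill_n)
                if significant
                else None,
                "group_true": analytic_group(spec, config, phs),
                "missing_phs_true": sorted(spec.missing_phs),
            }
        )
    return lists, pd.DataFrame(rows)


def _grid_positions(index: int, n_cols: int = 16) -> tuple[float, float]:
    """Well-separated base peak positions on a (δH, δN) lattice."""
    row, col = divmod(index, n_cols)
    return 5.8 + 0.38 * col, 101.5 + 2.2 * row


def uniform_titration_scenario(
    n_residues: int,
    pka: float,
    # amplitudes clear the OR significance rule even when only half the
    # transition falls inside the pH window (endpoint span 0.5)
    dh_amp: float = 0.12,
    dn_amp: float = 1.2,
    subunit: str = "NBS",
    sigma_h: float = 0.0,
    sigma_n: float = 0.0,
    seed: int = DEFAULT_SEED,
    ph_grid: Sequence[float] = (3.0, 4.0, 5.0, 6.0, 7.0),
) -> TitrationScenario:
    """All residues share one pKa and amplitude — classifier test bed."""
    residues = tuple(
        ResidueSpec(
            subunit,
            i + 1,
            pka=pka,
            h_base=_grid_positions(i)[0],
            n_base=_grid_positions(i)[1],
            dh_amp=dh_amp,
            dn_amp=dn_amp,
        )
        for i in range(n_residues)
    )
    return TitrationScenario(
        residues, tuple(ph_grid), sigma_h, sigma_n, seed
    )


# residues of the emulated screen (per-subunit 1-based numbering)
NAS_LENGTH, NBS_LENGTH = 113, 114
EXCHANGE_NAS = (29, 52)
EXCHANGE_NBS = (27, 28, 29, 30, 47, 48, 49, 52, 53, 72)
_NAMED_TYPES = {
    ("NAS", 21): "Y", ("NAS", 29): "C", ("NAS", 36): "H", ("NAS", 52): "C",
    ("NBS", 9): "T", ("NBS", 11): "H", ("NBS", 14): "H", ("NBS", 27): "N",
    ("NBS", 28): "K", ("NBS", 29): "C", ("NBS", 30): "N", ("NBS", 46): "D",
    ("NBS", 47): "R", ("NBS", 48): "R", ("NBS", 49): "G", ("NBS", 52): "C",
    ("NBS", 53): "R", ("NBS", 54): "L", ("NBS", 65): "Y", ("NBS", 66): "D",
    ("NBS", 72): "V", ("NBS", 94): "F",
}
# group-B members called out by the screen: shift change mainly at pH 5-7
_NAS_GROUP_B = (21, 36, 40, 44, 60, 70, 80, 90, 100, 110)
_NBS_GROUP_B = (9, 11, 14, 54, 65, 2, 40, 60, 100)
# NBS 94 titrates early (group A) yet keeps a significant 5-7 tail
_SPECIAL_A_PKA = {("NBS", 94): 4.8}


def reference_screen_scenario(
    sigma_h: float = 0.0,
    sigma_n: float = 0.0,
    seed: int = DEFAULT_SEED,
    exchange_missing_phs: frozenset[float] = frozenset({5.0, 6.0, 7.0}),
) -> TitrationScenario:
    """Two-subunit screen emulation: 36 NAS + 33 NBS significant residues.

    Group-A residues titrate with pKa 4.0, group-B with pKa 6.0 (carboxylate
    vs histidine regimes); amplitudes alternate between ¹H-dominated and
    ¹⁵N-dominated so both arms of the OR significance rule are exercised.
    Exchange-broadened residues are visible in the acidic spectra and vanish
    at the listed pH values.
    """
    exchange = {("NAS", r) for r in EXCHANGE_NAS}
    exchange |= {("NBS", r) for r in EXCHANGE_NBS}

    def pick_group_a(subunit: str, length: int, group_b, n_sig: int):
        taken = set(group_b) | {r for s, r in exchange if s == subunit}
        taken |= {r for (s, r) in _SPECIAL_A_PKA if s == subunit}
        out = []
        r = 1
        while len(out) < n_sig - len(group_b) - sum(
            1 for (s, _) in _SPECIAL_A_PKA if s == subunit
        ):
            if r not in taken:
                out.append(r)
            r += 3  # spread group-A members along the chain
            if r > length:
                raise ValueError("chain too short for requested counts")
        return tuple(out)

    nas_a = pick_group_a("NAS", NAS_LENGTH, _NAS_GROUP_B, 36)
    nbs_a = pick_group_a("NBS", NBS_LENGTH, _NBS_GROUP_B, 33)

    residues = []
    idx = 0
    for subunit, length, group_a, group_b in (
        ("NAS", NAS_LENGTH, nas_a, _NAS_GROUP_B),
        ("NBS", NBS_LENGTH, nbs_a, _NBS_GROUP_B),
    ):
        for num in range(1, length + 1):
            key = (subunit, num)
            h0, n0 = _grid_positions(idx)
            idx += 1
            rtype = _NAMED_TYPES.get(key, "X")
            missing = (
                exchange_missing_phs if key in exchange else frozenset()
            )
            if key in _SPECIAL_A_PKA:
                pka, dh, dn = _SPECIAL_A_PKA[key], 0.10, 1.0
            elif num in group_a and key not in exchange:
                pka = 4.0
                dh, dn = (0.10, 0.3) if num % 2 else (0.03, 1.0)
            elif num in group_b and key not in exchange:
                pka = 6.0
                dh, dn = (0.12, 0.4) if num % 2 else (0.04, 1.2)
            else:
                # below-threshold drift or static; exchange residues also
                # drift sub-threshold so their disappearance is the only cue
                pka, dh, dn = (4.5, 0.02, 0.2) if num % 4 == 0 else (None, 0.0, 0.0)
            residues.append(
                ResidueSpec(
                    subunit, num, rtype, pka=pka, h_base=h0, n_base=n0,
                    dh_amp=dh, dn_amp=dn, missing_phs=missing,
                )
            )
    return TitrationScenario(tuple(residues), (3.0, 4.0, 5.0, 6.0, 7.0),
                             sigma_h, sigma_n, seed)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def generate_structure(
    chains: dict[str, list[tuple[int, str, np.ndarray]]],
) -> StructureModel:
    """Build a :class:`StructureModel` from explicit residue coordinates.

    ``chains`` maps subunit label → list of (residue_number, one-letter
    type, (n_atoms, 3) coordinate array in Å); all pairwise distances are
    therefore known analytically by construction.
    """
    model = StructureModel()
    for subunit, entries in chains.items():
        for num, rtype, coords in entries:
            coords = np.atleast_2d(np.asarray(coords, dtype=float))
            model.residues[(subunit, num)] = Residue3D(subunit, num, rtype, coords)
    return model


def random_structure(
    rng: np.random.Generator,
    n_per_chain: int = 8,
    atoms_per_residue: int = 3,
    box: float = 25.0,
    separation: float = 0.0,
    subunits: tuple[str, str] = ("NAS", "NBS"),
) -> StructureModel:
    """Random two-chain toy structure (oracle test bed for distance code)."""
    chains: dict[str, list[tuple[int, str, np.ndarray]]] = {}
    for ci, sub in enumerate(subunits):
        entries = []
        offset = np.array([ci * (box + separation), 0.0, 0.0])
        for num in range(1, n_per_chain + 1):
            center = rng.uniform(0, box, size=3) + offset
            coords = center + rng.normal(0, 1.0, size=(atoms_per_residue, 3))
            rtype = "H" if rng.random() < 0.15 else "A"
            entries.append((num, rtype, coords))
        chains[sub] = entries
    return generate_structure(chains)


def write_structure_pdb(model: StructureModel, path) -> None:
    """Serialize a toy model as a PDB file (CA/CB/CG pseudo-atoms)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    gm = gemmi.Model("1")
    chain_names = {}
    for key in sorted(model.residues):
        sub = key[0]
        if sub not in chain_names:
            chain_names[sub] = chr(ord("A") + len(chain_names))
    chains = {sub: gemmi.Chain(name) for sub, name in chain_names.items()}
    atom_names = ["CA", "CB", "CG", "CD", "CE", "CZ", "NZ", "OD"]
    for key in sorted(model.residues):
        r = model.residues[key]
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(r.residue_type, "GLY")
        res.seqid = gemmi.SeqId(r.residue_number, " ")
        for i, xyz in enumerate(r.coords):
            atom = gemmi.Atom()
            atom.name = atom_names[i % len(atom_names)]
            atom.element = gemmi.Element(atom.name[0])
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            res.add_atom(atom)
        chains[r.subunit].add_residue(res)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(Path(path)))


def _blob(center, n_atoms: int = 3, spread: float = 0.8) -> np.ndarray:
    """Small deterministic atom cluster around a residue center."""
    offsets = np.array(
        [[0, 0, 0], [spread, 0, 0], [0, spread, 0], [0, 0, spread]]
    )[:n_atoms]
    return np.asarray(center, dtype=float) + offsets


def reference_screen_structure() -> tuple[StructureModel, dict]:
    """Clamshell-like two-chain layout with the screen's marker residues.

    Geometry (all coordinates in Å, analytically known):

    * an inter-chain interface strip at x ≈ 0 (contacts < 5 Å);
    * a histidine patch (NAS His36, NBS His11/His14) with NAS Tyr21 beside
      it — the pH-dependent activation interface;
    * the affinity patch (NBS Arg48/Tyr65/Val72/Phe94) ~25 Å away on the
      other face of the basic subunit;
    * group-B residues placed within 8 Å of the histidine patch.
    """
    nas: list[tuple[int, str, np.ndarray]] = []
    nbs: list[tuple[int, str, np.ndarray]] = []

    # interface strip: paired residues across x=0, 4.0 A apart
    for i, num in enumerate((5, 6, 7, 8)):
        y = 6.0 * i
        nas.append((num, "A", _blob([-2.0, y, 0.0])))
        nbs.append((num + 80, "A", _blob([2.0, y, 0.0])))

    # activation patch: His cluster + Tyr21 (NAS side, near the rim)
    nas.append((36, "H", _blob([-4.0, -8.0, 6.0])))
    nbs.append((11, "H", _blob([1.0, -8.0, 6.0])))
    nbs.append((14, "H", _blob([4.0, -10.0, 6.0])))
    nas.append((21, "Y", _blob([-6.0, -12.0, 6.0])))

    # group-B reporters within 8 A of a histidine
    nbs.append((9, "T", _blob([6.0, -6.0, 6.0])))
    nbs.append((54, "L", _blob([0.0, -13.0, 9.0])))
    nbs.append((65, "Y", _blob([8.0, -13.0, 4.0])))

    # affinity patch ~25 A away on the opposite face of NBS
    nbs.append((48, "R", _blob([20.0, 14.0, -6.0])))
    nbs.append((72, "V", _blob([23.0, 12.0, -4.0])))
    nbs.append((94, "F", _blob([20.0, 18.0, -8.0])))
    # Tyr65 belongs functionally to the affinity set but sits near the His
    # patch in this toy layout only through its side chain; keep it above.

    # filler core residues away from everything interesting
    for i, num in enumerate((60, 61, 62)):
        nas.append((num, "A", _blob([-15.0, 10.0 + 5 * i, -10.0])))

    model = generate_structure({"NAS": nas, "NBS": nbs})
    labels = {
        ("NAS", 21): "pH_dependency",
        ("NAS", 36): "pH_dependency",
        ("NBS", 11): "pH_dependency",
        ("NBS", 14): "pH_dependency",
        ("NBS", 48): "affinity",
        ("NBS", 72): "affinity",
        ("NBS", 94): "affinity",
    }
    return model, {"functional_labels": labels}


# ---------------------------------------------------------------------------
# cell assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """Ground truth for one protein variant in the cell assay."""

    ec50_um: float
    hill: float = 1.5
    top_acidic: float = 1.0
    top_neutral: float = 0.2
    antagonism_strength: float = 0.0  # fractional suppression at saturation

    def top_at(self, ph: float, ph_neutral: float = 7.4) -> float:
        return self.top_neutral if ph >= ph_neutral else self.top_acidic


@dataclass(frozen=True)
class AssayScenario:
    variants: dict[str, VariantSpec]
    n_cells: int = 0  # 0 -> noiseless
    conc_grid_um: tuple[float, ...] = tuple(
        float(c) for c in np.logspace(-2, 1.3, 8)
    )
    ph_acidic: float = 6.3
    ph_neutral: float = 7.4
    ph_basic: float = 8.0
    agonist_reference_response: float = 0.6  # co-applied agonist, alone
    seed: int = DEFAULT_SEED


def reference_assay_scenario(n_cells: int = 0, seed: int = DEFAULT_SEED) -> AssayScenario:
    """Variant panel with the screen's EC50 ladder and effect directions.

    WT-like: strongly pH-dependent agonist.  Histidine-site variants
    (H11A-like, H36A-like, H14A-like, Y21A-like): raised neutral-pH response,
    H11A fully pH-independent.  Affinity variants shift EC50 up or down and
    change antagonist strength in the same direction, without touching the
    pH dependency.
    """
    v = {
        "WT": VariantSpec(1.24, antagonism_strength=0.50),
        "H11A": VariantSpec(2.12, top_acidic=0.80, top_neutral=0.80),
        "H36A": VariantSpec(1.20, top_acidic=0.90, top_neutral=0.65),
        "H14A": VariantSpec(1.20, top_acidic=0.90, top_neutral=0.65),
        "Y21A": VariantSpec(1.03, top_acidic=0.90, top_neutral=0.70),
        "R48A": VariantSpec(0.31, antagonism_strength=0.85),
        "V72A": VariantSpec(0.84, antagonism_strength=0.75),
        "Y65A": VariantSpec(6.90, antagonism_strength=0.25),
        "F94A": VariantSpec(3.79, antagonism_strength=0.30),
    }
    return AssayScenario(variants=v, n_cells=n_cells, seed=seed)


def _noisy_fractions(
    p: np.ndarray, n_cells: int, rng: np.random.Generator
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Binomial counting noise on responding-cell fractions."""
    if n_cells <= 0:
        return p.copy(), None
    clipped = np.clip(p, 0.0, 1.0)
    counts = rng.binomial(n_cells, clipped)
    frac = counts / n_cells
    se = np.sqrt(np.maximum(clipped * (1 - clipped), 1e-4) / n_cells)
    return frac, se


def generate_assay(
    scenario: AssayScenario,
) -> tuple[dict[tuple[str, float], ResponseTable], dict] :
    """Dose–response tables per (variant, pH) plus antagonist-mode tables.

    Returns ``(tables, truth)`` where ``tables`` holds agonist-mode tables at
    the acidic and neutral pH for each variant, and ``truth`` carries the
    scenario itself plus antagonist-mode mixture tables at the basic pH
    (test protein co-applied with a saturating pH-independent agonist) and
    the agonist-alone reference table.
    """
    rng = np.random.default_rng(scenario.seed)
    conc = np.asarray(scenario.conc_grid_um, dtype=float)
    tables: dict[tuple[str, float], ResponseTable] = {}
    for name, spec in scenario.variants.items():
        for ph in (scenario.ph_acidic, scenario.ph_neutral):
            top = spec.top_at(ph, scenario.ph_neutral)
            ideal = hill_curve(conc, top, spec.ec50_um, spec.hill)
            resp, se = _noisy_fractions(ideal, scenario.n_cells, rng)
            tables[(name, ph)] = ResponseTable(name, ph, conc, resp, se)

    # antagonist mode at basic pH: suppression of a fixed co-agonist response
    ref = scenario.agonist_reference_response
    mixtures: dict[str, ResponseTable] = {}
    for name, spec in scenario.variants.items():
        if spec.antagonism_strength <= 0:
            continue
        occ = conc / (conc + spec.ec50_um)
        ideal = ref * (1.0 - spec.antagonism_strength * occ)
        resp, se = _noisy_fractions(ideal, scenario.n_cells, rng)
        mixtures[name] = ResponseTable(name, scenario.ph_basic, conc, resp, se)
    alone_ideal = np.full_like(conc, ref)
    alone_resp, alone_se = _noisy_fractions(alone_ideal, scenario.n_cells, rng)
    agonist_alone = ResponseTable(
        "agonist_alone", scenario.ph_basic, conc, alone_resp, alone_se
    )
    truth = {
        "scenario": scenario,
        "mixture_tables": mixtures,
        "agonist_alone": agonist_alone,
    }
    return tables, truth


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

def sphere_rg(radius: float) -> float:
    """Radius of gyration of a homogeneous sphere: Rg = R·√(3/5)."""
    return radius * np.sqrt(3.0 / 5.0)


def sphere_intensity(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Sphere form factor I(q) = I₀·[3(sin x − x cos x)/x³]², x = qR."""
    x = np.asarray(q, dtype=float) * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    f = np.where(x == 0, 1.0, f)
    return i0 * f**2


def generate_saxs(
    radius: float,
    noise: float = 0.0,
    seed: int = DEFAULT_SEED,
    q_min: float = 0.006,
    q_max: float = 0.35,
    n_points: int = 180,
    i0: float = 1.0,
):
    """Sphere-form-factor profile with multiplicative Gaussian noise.

    Returns ``(profile, truth)`` with ``truth['rg'] = R√(3/5)``.  When
    ``noise > 0`` the per-point σ column is set to ``noise·I``.
    """
    from .saxs import SAXSProfile

    if radius <= 0:
        raise ValueError("radius must be positive")
    q = np.linspace(q_min, q_max, n_points)
    ideal = sphere_intensity(q, radius, i0)
    if noise > 0:
        rng = np.random.default_rng(seed)
        intensity = ideal * (1.0 + rng.normal(0.0, noise, size=q.shape))
        intensity = np.maximum(intensity, 1e-12 * i0)
        sigma = noise * ideal
    else:
        intensity, sigma = ideal, None
    profile = SAXSProfile(q, intensity, sigma)
    truth = {"radius": radius, "rg": float(sphere_rg(radius)), "i0": i0}
    return profile, truth
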