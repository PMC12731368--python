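"""Photon-physics lookup tables: mass attenuation, emission lines, cross-sections.

All quantities come from plain-text tables bundled with the package so results
are deterministic and reproducible offline.  Mass attenuation coefficients are
stored per element on a fixed 5-100 keV grid and interpolated log-log between
nodes, the standard scheme for photon cross-sections away from absorption
edges.  Composite materials are evaluated with the weight-fraction mixture
rule.  Users can drop in alternative tables with the same TSV layout via
:meth:`AttenuationTable.from_tsv` and a custom material registry.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Material",
    "AttenuationTable",
    "EmissionLine",
    "BelowEdgeError",
    "EnergyRangeError",
    "UnknownLineError",
    "get_material",
    "material_names",
    "mass_attenuation",
    "fluorescence_cross_section",
    "line_energy",
    "emission_lines",
    "default_attenuation_table",
]


class EnergyRangeError(ValueError):
    """Requested energy lies outside the tabulated grid."""


class BelowEdgeError(ValueError):
    """Excitation energy below the absorption edge of the requested shell."""


class UnknownLineError(KeyError):
    """Unknown element / line-label combination."""


def _data_text(name: str) -> str:
    return resources.files("xfiquant.data").joinpath(name).read_text()


@dataclass(frozen=True)
class Material:
    """A material as an element -> weight-fraction map plus nominal density.

    Weight fractions must be positive and sum to 1 within 1e-9; the nominal
    density (g/cm^3) is the constant density assigned to voxels of this class
    in ``density_mode="nominal"``.
    """

    name: str
    composition: Mapping[str, float]
    nominal_density: float
    display_name: str = ""

    def __post_init__(self):
        comp = dict(self.composition)
        if not comp:
            raise ValueError("material composition is empty")
        if any(w <= 0 for w in comp.values()):
            raise ValueError(f"{self.name}: weight fractions must be positive")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: weight fractions sum to {total}, not 1")
        if self.nominal_density <= 0:
            raise ValueError(f"{self.name}: nominal density must be positive")
        object.__setattr__(self, "composition", MappingProxyType(comp))

    @staticmethod
    def normalized(name, composition, nominal_density, display_name=""):
        total = sum(composition.values())
        comp = {k: v / total for k, v in composition.items()}
        return Material(name, comp, nominal_density, display_name)


class AttenuationTable:
    """Elemental mass attenuation coefficients mu/rho (cm^2/g) on an energy grid.

    Interpolation is linear in (log E, log mu); queries exactly at a grid node
    return the stored value.  Queries outside the grid raise
    :class:`EnergyRangeError`.
    """

    def __init__(self, energies_kev: np.ndarray, element_tables: Mapping[str, np.ndarray]):
        energies = np.asarray(energies_kev, dtype=float)
        if energies.ndim != 1 or len(energies) < 2 or np.any(np.diff(energies) <= 0):
            raise ValueError("energy grid must be 1-D and strictly increasing")
        self.energies = energies
        self._log_e = np.log(energies)
        self._tables = {}
        for sym, vals in element_tables.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != energies.shape:
                raise ValueError(f"{sym}: table shape mismatch")
            if np.any(vals <= 0):
                raise ValueError(f"{sym}: coefficients must be positive")
            self._tables[sym] = np.log(vals)

    @classmethod
    def from_tsv(cls, text: str) -> "AttenuationTable":
        energies: list[float] = []
        cols: dict[str, list[float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sym, e, v = line.split("\t")
            cols.setdefault(sym, []).append(float(v))
            if sym == next(iter(cols)):
                energies.append(float(e))
        grid = np.array(energies)
        return cls(grid, {s: np.array(v) for s, v in cols.items()})

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._tables)

    def _check_range(self, energy):
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energy_range
        if np.any(e < lo) or np.any(e > hi):
            raise EnergyRangeError(
                f"energy {energy} keV outside tabulated range [{lo}, {hi}] keV"
            )
        return e

    def element_mu_rho(self, symbol: str, energy):
        """Log-log interpolated mu/rho (cm^2/g) for a single element."""
        if symbol not in self._tables:
            raise KeyError(f"no attenuation table for element {symbol!r}")
        e = self._check_range(energy)
        out = np.exp(np.interp(np.log(e), self._log_e, self._tables[symbol]))
        return float(out) if np.isscalar(energy) else out

    def material_mu_rho(self, material: Material, energy):
        """Mixture-rule mu/rho: sum of weight-fraction-weighted elemental values."""
        e = self._check_range(energy)
        acc = np.zeros_like(np.asarray(e, dtype=float))
        for sym, w in material.composition.items():
            acc = acc + w * np.exp(np.interp(np.log(e), self._log_e, self._tables[sym]))
        return float(acc) if np.isscalar(energy) else acc


@functools.lru_cache(maxsize=1)
def default_attenuation_table() -> AttenuationTable:
    return AttenuationTable.from_tsv(_data_text("mu_rho_elements.tsv"))


@functools.lru_cache(maxsize=1)
def _registry() -> dict[str, Material]:
    doc = yaml.safe_load(_data_text("materials.yaml"))
    out = {}
    for name, entry in doc["materials"].items():
        out[name] = Material.normalized(
            name, entry["composition"], entry["nominal_density"],
            entry.get("display_name", name),
        )
    return out


def get_material(name: str) -> Material:
    reg = _registry()
    if isinstance(name, Material):
        return name
    if name not in reg:
        raise KeyError(f"unknown material {name!r}; known: {sorted(reg)}")
    return reg[name]


def material_names() -> tuple[str, ...]:
    return tuple(_registry())


def mass_attenuation(material, energy, table: AttenuationTable | None = None):
    """mu/rho (cm^2/g) for a material (name or :class:`Material`) at energy keV."""
    table = table or default_attenuation_table()
    return table.material_mu_rho(get_material(material), energy)


# ---------------------------------------------------------------------------
# Emission lines and fluorescence production cross-sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionLine:
    element: str
    label: str          # e.g. "La1" (Siegbahn, ASCII)
    group: str          # fine-structure subgroup, e.g. "La", "Lb", "Ka"
    shell: str          # "K" or "L"
    energy: float       # keV
    rel_intensity: float  # relative to the strongest line of the shell

    def __post_init__(self):
        if self.energy <= 0 or self.rel_intensity <= 0:
            raise ValueError("line energy and relative intensity must be positive")


@functools.lru_cache(maxsize=1)
def _lines() -> tuple[EmissionLine, ...]:
    out = []
    for line in _data_text("emission_lines.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, lab, grp, shell, e, ri = line.split("\t")
        out.append(EmissionLine(el, lab, grp, shell, float(e), float(ri)))
    return tuple(out)


def emission_lines(element: str, shell: str | None = None,
                   group: str | None = None) -> tuple[EmissionLine, ...]:
    """Tabulated lines of an element, optionally restricted to a shell or group."""
    sel = tuple(
        l for l in _lines()
        if l.element == element
        and (shell is None or l.shell == shell)
        and (group is None or l.group == group)
    )
    if not sel:
        raise UnknownLineError(
            f"no tabulated lines for {element} (shell={shell}, group={group})"
        )
    return sel


def line_energy(element: str, line: str) -> float:
    """Energy (keV) of a tabulated emission line, e.g. line_energy('Au', 'La1')."""
    for l in _lines():
        if l.element == element and l.label == line:
            return l.energy
    valid = sorted({l.label for l in _lines() if l.element == element})
    raise UnknownLineError(
        f"unknown line {line!r} for element {element!r}; valid labels: {valid}"
    )


@functools.lru_cache(maxsize=1)
def _groups() -> dict[tuple[str, str], tuple[float, float, float, float]]:
    out = {}
    for line in _data_text("fluorescence_groups.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, shell, edge, eref, sref, p = line.split("\t")
        out[(el, shell)] = (float(edge), float(eref), float(sref), float(p))
    return out


def absorption_edge(element: str, shell: str) -> float:
    """Highest subshell edge energy (keV) of the given shell."""
    try:
        return _groups()[(element, shell)][0]
    except KeyError:
        raise UnknownLineError(f"no cross-section data for {element} {shell}-shell")


def branching_fractions(element: str, shell: str) -> dict[str, float]:
    """Per-line share of the shell's total radiative intensity (sums to 1)."""
    lines = emission_lines(element, shell=shell)
    total = sum(l.rel_intensity for l in lines)
    return {l.label: l.rel_intensity / total for l in lines}


def fluorescence_cross_section(element: str, shell_or_line: str,
                               excitation_energy: float, *, strict: bool = True) -> float:
    """Fluorescence production cross-section sigma_f (cm^2 per g of element).

    ``shell_or_line`` may be a shell ("L", "K"), a subgroup ("La", "Ka"), or a
    single line label ("La1"); sub-shell selections return the branching share
    of the shell total.  Below the shell edge the cross-section is zero; with
    ``strict=True`` (default) this raises :class:`BelowEdgeError` instead of
    silently returning 0.
    """
    shells = {s for (el, s) in _groups() if el == element}
    if not shells:
        raise UnknownLineError(f"no cross-section data for element {element!r}")
    if shell_or_line in shells:
        shell, share = shell_or_line, 1.0
    else:
        lines = [l for l in _lines() if l.element == element
                 and shell_or_line in (l.group, l.label)]
        if not lines:
            raise UnknownLineError(
                f"unknown shell/group/line {shell_or_line!r} for {element!r}"
            )
        shell = lines[0].shell
        frac = branching_fractions(element, shell)
        share = sum(frac[l.label] for l in lines)
    edge, eref, sref, p = _groups()[(element, shell)]
    if excitation_energy <= edge:
        if strict:
            raise BelowEdgeError(
                f"{excitation_energy} keV is below the {element} {shell}-shell "
                f"edge at {edge} keV"
            )
        return 0.0
    return share * sref * (eref / excitation_energy) ** p


@functools.lru_cache(maxsize=1)
def default_hu_ranges() -> tuple[tuple[float, float, str], ...]:
    """The default HU classification intervals from the bundled registry."""
    doc = yaml.safe_load(_data_text("materials.yaml"))
    return tuple((float(lo), float(hi), str(name)) for lo, hi, name in doc["hu_table"])
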