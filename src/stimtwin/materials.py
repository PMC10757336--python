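"""Material property registry and frequency-dependent complex admittivity.

Every domain in the twin (culture medium, electrode films, printed bioreactor
parts, scaffold polymer) is described by a :class:`MaterialSpec` holding its
electrical properties and, for fluids, its viscous properties.  The built-in
registry carries the values used throughout the solvers; users can extend or
override it from a YAML file without touching code.

All quantities are SI: conductivity in S/m, dynamic viscosity in Pa.s,
density in kg/m^3.  The medium's 6.89e-4 Pa.s entry is a *dynamic* viscosity
(the units identify it as such, matching water at 37 C) even though some
property tables label it kinematic; see docs/methods.md.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "EPSILON_0",
    "MaterialSpec",
    "MaterialRegistry",
    "default_registry",
    "complex_conductivity",
]

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.854e-12


@dataclass(frozen=True)
class MaterialSpec:
    """Electrical and (optionally) fluid properties of one material.

    Parameters
    ----------
    name : str
        Registry label.
    sigma : float
        Electric conductivity, S/m.  Must be >= 0.
    eps_r : float
        Relative permittivity, dimensionless.  Must be >= 1.
    mu : float, optional
        Dynamic viscosity, Pa.s.  Only meaningful for fluids.
    rho : float, optional
        Density, kg/m^3.  Only meaningful for fluids.
    """

    name: str
    sigma: float
    eps_r: float
    mu: float | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"{self.name}: conductivity must be >= 0, got {self.sigma}")
        if self.eps_r < 1:
            raise ValueError(f"{self.name}: relative permittivity must be >= 1, got {self.eps_r}")
        if (self.mu is None) != (self.rho is None):
            raise ValueError(f"{self.name}: fluids need both mu and rho")
        if self.mu is not None and self.mu <= 0:
            raise ValueError(f"{self.name}: dynamic viscosity must be > 0, got {self.mu}")
        if self.rho is not None and self.rho <= 0:
            raise ValueError(f"{self.name}: density must be > 0, got {self.rho}")

    @property
    def is_fluid(self) -> bool:
        return self.mu is not None


def complex_conductivity(material: MaterialSpec, f: float) -> complex:
    """Complex admittivity sigma* = sigma + i * 2*pi*f * eps0 * eps_r, S/m.

    Under the quasistatic approximation the frequency-domain current
    conservation equation uses this admittivity in place of the DC
    conductivity; the imaginary part carries the displacement (capacitive)
    current.  At f = 0 the DC conductivity is returned exactly.

    Raises
    ------
    ValueError
        If ``f`` is negative.
    """
    if f < 0:
        raise ValueError(f"frequency must be >= 0, got {f}")
    return complex(material.sigma, 2.0 * math.pi * f * EPSILON_0 * material.eps_r)


class MaterialRegistry(Mapping):
    """Immutable-by-convention mapping from label to :class:`MaterialSpec`."""

    def __init__(self, specs: dict[str, MaterialSpec] | None = None) -> None:
        self._specs: dict[str, MaterialSpec] = dict(specs or {})

    def __getitem__(self, name: str) -> MaterialSpec:
        try:
            return self._specs[name]
        except KeyError:
            valid = ", ".join(sorted(self._specs))
            raise KeyError(f"unknown material {name!r}; registered labels: {valid}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def get_material(self, name: str) -> MaterialSpec:
        """Alias of item access with the descriptive error message."""
        return self[name]

    def add(self, spec: MaterialSpec, *, overwrite: bool = False) -> None:
        if spec.name in self._specs and not overwrite:
            raise ValueError(f"material {spec.name!r} already registered")
        self._specs[spec.name] = spec

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {}
        for name, s in self._specs.items():
            d: dict = {"sigma": s.sigma, "eps_r": s.eps_r}
            if s.mu is not None:
                d["mu"] = s.mu
                d["rho"] = s.rho
            out[name] = d
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "MaterialRegistry":
        specs = {
            name: MaterialSpec(name=name, **dict(entry)) for name, entry in data.items()
        }
        return cls(specs)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MaterialRegistry":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_registry() -> MaterialRegistry:
    """Built-in material table.

    medium
        Osteogenic culture medium at 37 C (conductive saline; water-like
        viscosity).
    ITO
        Indium tin oxide conductor coating of the electrode films.
    PET
        Polyester carrier film of the electrodes; the capacitive dielectric
        barrier between ITO and medium.
    C8
        PLA composite used for the printed bioreactor parts (chamber,
        holders).
    PCL
        Polycaprolactone scaffold polymer.
    """
    reg = MaterialRegistry()
    reg.add(MaterialSpec("medium", sigma=1.5, eps_r=80.1, mu=6.89e-4, rho=9.94e2))
    reg.add(MaterialSpec("ITO", sigma=1.0e6, eps_r=1.0))
    reg.add(MaterialSpec("PET", sigma=1.0e-21, eps_r=3.0))
    reg.add(MaterialSpec("C8", sigma=1.0e-21, eps_r=2.7))
    reg.add(MaterialSpec("PCL", sigma=1.0e-13, eps_r=3.2))
    return reg
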