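"""Synthetic consequence database: chemicals, leak scenarios, and a surrogate blast model.

The real study behind this kind of pipeline drives a commercial process-hazard
simulator to map (chemical, release condition) onto an "explosion diameter":
the spatial extent of the zone where blast overpressure reaches a target level
(2068 Pa here).  This module replaces that engine with a fully documented
TNT-equivalency surrogate so that the entire modelling pipeline is exercisable
and testable end-to-end without commercial software.

Surrogate definition (noise off), documented verbatim so it can be audited:

    released mass      m_c = density * quantity * r_release
    release fraction   r_release = (leak_size / 50)**0.5
                                   * (pressure / 1000)**0.25
                                   * (0.2 + 0.8 * logistic((T - T_b) / 25))
    TNT-equivalent     W = eta * m_c * dH_c / E_TNT          [kg TNT]
    scaled distance    Z* solves the Sadovsky surface-burst correlation
                       dp(Z) [kPa] = 95/Z + 390/Z**2 + 1300/Z**3
                       at dp = target_overpressure
    diameter           D = 2 * Z* * W**(1/3)                 [m]

optionally multiplied by lognormal(0, noise_sigma) noise.  The diameter is
strictly increasing in leak size, pressure, quantity, temperature and heat of
combustion when the noise is off.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "ChemicalRecord",
    "ScenarioGrid",
    "LeakScenario",
    "ExplosionRecord",
    "SurrogateConfig",
    "TEMPLATE_LIBRARY",
    "standard_grid",
    "enumerate_scenarios",
    "surrogate_diameter",
    "sadovsky_scaled_distance",
    "make_synthetic_chemicals",
    "generate_dataset",
    "chemicals_to_frame",
    "dataset_to_frame",
]


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical: identity (SMILES), bulk properties, and a descriptor vector.

    density is the liquid density in kg/m3, heat_of_combustion in MJ/kg and
    boiling_point in degrees C.  Descriptors are consumed as data (in the
    emulated study they come from quantum-chemistry calculations).
    """

    chem_id: str
    smiles: str
    density: float
    heat_of_combustion: float
    boiling_point: float
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"{self.chem_id}: SMILES must be non-empty")
        if not self.density > 0:
            raise ValueError(f"{self.chem_id}: density must be positive")
        if not self.heat_of_combustion > 0:
            raise ValueError(f"{self.chem_id}: heat_of_combustion must be positive")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError(f"{self.chem_id}: descriptor names must be unique")


@dataclass(frozen=True)
class LeakScenario:
    """One release condition: temperature (C), pressure (psi), leak size (in), quantity (m3)."""

    temperature: float
    pressure: float
    leak_size: float
    quantity: float

    def __post_init__(self) -> None:
        for name in ("pressure", "leak_size", "quantity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"LeakScenario.{name} must be strictly positive")


@dataclass(frozen=True)
class ScenarioGrid:
    """Axes of a full-factorial release-condition design."""

    temperatures: tuple[float, ...]
    pressures: tuple[float, ...]
    leak_sizes: tuple[float, ...]
    quantities: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("temperatures", "pressures", "leak_sizes", "quantities"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"ScenarioGrid.{name} must be non-empty")
            if not all(np.isfinite(v) for v in vals):
                raise ValueError(f"ScenarioGrid.{name} must be finite")
        if any(v <= 0 for v in self.pressures + self.leak_sizes + self.quantities):
            raise ValueError("pressures, leak sizes and quantities must be positive")


@dataclass(frozen=True)
class ExplosionRecord:
    """One simulated consequence: chemical x scenario -> explosion diameter in metres."""

    chem_id: str
    scenario: LeakScenario
    diameter: float
    log_diameter: float | None = None

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")


@dataclass(frozen=True)
class SurrogateConfig:
    """Parameters of the TNT-equivalency surrogate.

    yield_factor is the fraction of combustion energy contributing to the
    blast (a conventional explosion-yield value of a few percent),
    tnt_energy the specific blast energy of TNT in MJ/kg, and
    target_overpressure the endpoint overpressure in Pa that defines the
    reported diameter.  noise_sigma is the standard deviation of
    multiplicative lognormal noise applied to the diameter.
    """

    yield_factor: float = 0.03
    tnt_energy: float = 4.68
    target_overpressure: float = 2068.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.yield_factor <= 1:
            raise ValueError("yield_factor must lie in (0, 1]")
        if not self.tnt_energy > 0:
            raise ValueError("tnt_energy must be positive")
        if not self.target_overpressure > 0:
            raise ValueError("target_overpressure must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def standard_grid() -> ScenarioGrid:
    """The 4 x 3 x 3 x 3 full-factorial release-condition design (108 scenarios)."""
    return ScenarioGrid(
        temperatures=(0.0, 20.0, 50.0, 100.0),
        pressures=(100.0, 500.0, 1000.0),
        leak_sizes=(10.0, 25.0, 50.0),
        quantities=(10.0, 20.0, 100.0),
    )


def enumerate_scenarios(grid: ScenarioGrid) -> list[LeakScenario]:
    """Full Cartesian product in lexicographic (temperature, pressure, leak, quantity) order."""
    return [
        LeakScenario(t, p, s, q)
        for t, p, s, q in itertools.product(
            grid.temperatures, grid.pressures, grid.leak_sizes, grid.quantities
        )
    ]


def sadovsky_scaled_distance(target_overpressure_pa: float) -> float:
    """Scaled distance Z* (m/kg^(1/3)) at which the Sadovsky surface-burst
    correlation dp(Z) = 95/Z + 390/Z^2 + 1300/Z^3 (kPa) equals the target."""
    dp_kpa = target_overpressure_pa / 1000.0

    def f(z: float) -> float:
        return 95.0 / z + 390.0 / z**2 + 1300.0 / z**3 - dp_kpa

    try:
        return brentq(f, 1e-3, 1e5, xtol=1e-10, rtol=1e-12)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ArithmeticError(
            f"scaled-distance root find failed for dp={dp_kpa} kPa: {exc}"
        ) from exc


def _release_fraction(scen: LeakScenario, boiling_point: float) -> float:
    return (
        (scen.leak_size / 50.0) ** 0.5
        * (scen.pressure / 1000.0) ** 0.25
        * (0.2 + 0.8 * expit((scen.temperature - boiling_point) / 25.0))
    )


def surrogate_diameter(
    chem: ChemicalRecord,
    scen: LeakScenario,
    cfg: SurrogateConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Explosion diameter (m) from the TNT-equivalency surrogate (module docstring)."""
    cfg = cfg or SurrogateConfig()
    m_c = chem.density * scen.quantity * _release_fraction(scen, chem.boiling_point)
    w_tnt = cfg.yield_factor * m_c * chem.heat_of_combustion / cfg.tnt_energy
    if not w_tnt > 0:
        raise ValueError(
            f"non-positive TNT-equivalent mass {w_tnt!r} for {chem.chem_id}"
        )
    z_star = sadovsky_scaled_distance(cfg.target_overpressure)
    diameter = 2.0 * z_star * w_tnt ** (1.0 / 3.0)
    if cfg.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        diameter *= float(np.exp(cfg.noise_sigma * rng.standard_normal()))
    return float(diameter)


# Built-in library of real flammable species spanning 12 functional-group
# classes, with literature-plausible liquid density (kg/m3), net heat of
# combustion (MJ/kg) and normal boiling point (C).  Values are rounded
# handbook figures; they define the synthetic study conditions, not a
# thermochemical reference.
TEMPLATE_LIBRARY: tuple[tuple[str, str, str, float, float, float], ...] = (
    # (chem_id, smiles, class, density, dH_c, T_b)
    ("pentane", "CCCCC", "alkane", 626.0, 45.4, 36.0),
    ("hexane", "CCCCCC", "alkane", 659.0, 44.7, 69.0),
    ("heptane", "CCCCCCC", "alkane", 684.0, 44.6, 98.0),
    ("octane", "CCCCCCCC", "alkane", 703.0, 44.4, 126.0),
    ("isopentane", "CC(C)CC", "alkane", 616.0, 45.2, 28.0),
    ("cyclohexane", "C1CCCCC1", "alkane", 779.0, 43.4, 81.0),
    ("pent-1-ene", "C=CCCC", "alkene", 640.0, 44.9, 30.0),
    ("hex-1-ene", "C=CCCCC", "alkene", 673.0, 44.6, 63.0),
    ("cyclohexene", "C1CCC=CC1", "alkene", 811.0, 43.0, 83.0),
    ("isoprene", "C=C(C)C=C", "alkene", 681.0, 43.8, 34.0),
    ("pent-1-yne", "C#CCCC", "alkyne", 690.0, 43.8, 40.0),
    ("hex-1-yne", "C#CCCCC", "alkyne", 715.0, 43.5, 71.0),
    ("methanol", "CO", "alcohol", 792.0, 19.9, 65.0),
    ("ethanol", "CCO", "alcohol", 789.0, 26.8, 78.0),
    ("propan-1-ol", "CCCO", "alcohol", 803.0, 30.7, 97.0),
    ("propan-2-ol", "CC(C)O", "alcohol", 786.0, 30.4, 82.0),
    ("butan-1-ol", "CCCCO", "alcohol", 810.0, 33.1, 118.0),
    ("benzene", "c1ccccc1", "aromatic", 877.0, 40.1, 80.0),
    ("toluene", "Cc1ccccc1", "aromatic", 867.0, 40.5, 111.0),
    ("ethylbenzene", "CCc1ccccc1", "aromatic", 867.0, 40.9, 136.0),
    ("p-xylene", "Cc1ccc(C)cc1", "aromatic", 861.0, 40.8, 138.0),
    ("styrene", "C=Cc1ccccc1", "aromatic", 906.0, 40.5, 145.0),
    ("ethylamine", "CCN", "amine", 689.0, 35.2, 17.0),
    ("propylamine", "CCCN", "amine", 717.0, 36.9, 48.0),
    ("diethylamine", "CCNCC", "amine", 707.0, 38.0, 55.0),
    ("butylamine", "CCCCN", "amine", 740.0, 38.0, 78.0),
    ("acetone", "CC(C)=O", "ketone", 784.0, 28.6, 56.0),
    ("butan-2-one", "CCC(C)=O", "ketone", 805.0, 31.5, 80.0),
    ("pentan-2-one", "CCCC(C)=O", "ketone", 809.0, 33.2, 102.0),
    ("cyclohexanone", "O=C1CCCCC1", "ketone", 948.0, 33.7, 156.0),
    ("diethyl-ether", "CCOCC", "ether", 713.0, 33.9, 35.0),
    ("thf", "C1CCOC1", "ether", 889.0, 32.2, 66.0),
    ("mtbe", "CC(C)(C)OC", "ether", 740.0, 35.2, 55.0),
    ("dipropyl-ether", "CCCOCCC", "ether", 736.0, 36.4, 90.0),
    ("methyl-formate", "COC=O", "ester", 974.0, 15.8, 32.0),
    ("methyl-acetate", "COC(C)=O", "ester", 932.0, 20.2, 57.0),
    ("ethyl-acetate", "CCOC(C)=O", "ester", 902.0, 23.5, 77.0),
    ("butyl-acetate", "CCCCOC(C)=O", "ester", 882.0, 28.0, 126.0),
    ("acetaldehyde", "CC=O", "aldehyde", 788.0, 25.1, 20.0),
    ("propanal", "CCC=O", "aldehyde", 805.0, 28.9, 48.0),
    ("butanal", "CCCC=O", "aldehyde", 802.0, 31.7, 75.0),
    ("acetic-acid", "CC(O)=O", "acid", 1049.0, 14.6, 118.0),
    ("propionic-acid", "CCC(O)=O", "acid", 990.0, 19.6, 141.0),
    ("acetonitrile", "CC#N", "nitrile", 786.0, 29.6, 82.0),
    ("propionitrile", "CCC#N", "nitrile", 772.0, 33.9, 97.0),
    ("acrylonitrile", "C=CC#N", "nitrile", 810.0, 32.0, 77.0),
)

#: Descriptor columns generated per chemical.  The "signal" columns are noisy
#: affine transforms of the heat of combustion or the boiling point (so the
#: descriptor table carries real, imperfect chemical information, as
#: quantum-chemistry descriptors would); the rest are pure noise, and one
#: column is zero for most chemicals to exercise the sparsity filter.
_DESCRIPTOR_SPEC = (
    # (name, source property, slope, intercept, noise sd)
    # Noise levels give descriptor-property correlations near 0.75, the
    # regime where single quantum-chemistry descriptors track bulk
    # properties imperfectly and the structural modality retains value.
    ("e_homo", "dhc", 0.004, -0.45, 0.030),
    ("heat_release_index", "dhc", 1.0, 0.0, 7.5),
    ("mol_weight_calc", "tb", 0.55, 60.0, 18.0),
    ("polarizability", "tb", 0.08, 5.0, 2.6),
    ("e_lumo", None, 0.0, 0.05, 0.02),
    ("dipole_moment", None, 0.0, 1.8, 0.7),
    ("quadrupole_zz", None, 0.0, -4.0, 1.5),
    ("entropy_298k", None, 0.0, 310.0, 25.0),
    ("rotational_const_a", None, 0.0, 0.9, 0.3),
    ("vib_freq_min", None, 0.0, 120.0, 40.0),
    ("homo_lumo_gap", "dhc", -0.004, 0.50, 0.032),
    ("zpe_sparse", None, 0.0, 0.0, 0.0),  # filled sparsely below
)


def make_synthetic_chemicals(n: int, seed: int = 0) -> list[ChemicalRecord]:
    """Draw ``n`` chemicals from the template library with a seeded descriptor table.

    Deterministic given the seed.  If ``n`` exceeds the library size the
    templates are reused with perturbed bulk properties (with a warning).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(TEMPLATE_LIBRARY))
    records: list[ChemicalRecord] = []
    if n > len(TEMPLATE_LIBRARY):
        warnings.warn(
            f"n={n} exceeds template capacity {len(TEMPLATE_LIBRARY)}; "
            "templates reused with perturbed properties",
            stacklevel=2,
        )
    for i in range(n):
        chem_id, smiles, _cls, rho, dhc, tb = TEMPLATE_LIBRARY[order[i % len(TEMPLATE_LIBRARY)]]
        if i >= len(TEMPLATE_LIBRARY):
            rho = rho * float(rng.uniform(0.9, 1.1))
            dhc = dhc * float(rng.uniform(0.92, 1.08))
            tb = tb + float(rng.uniform(-12.0, 12.0))
            chem_id = f"{chem_id}-v{i // len(TEMPLATE_LIBRARY) + 1}"
        desc: dict[str, float] = {}
        for name, src, slope, intercept, sd in _DESCRIPTOR_SPEC:
            base = {"dhc": dhc, "tb": tb, None: 0.0}[src]
            desc[name] = float(slope * base + intercept + sd * rng.standard_normal())
        # sparse column: non-zero for ~10% of chemicals only
        desc["zpe_sparse"] = float(rng.uniform(50.0, 90.0)) if rng.random() < 0.1 else 0.0
        records.append(
            ChemicalRecord(
                chem_id=chem_id,
                smiles=smiles,
                density=float(rho),
                heat_of_combustion=float(dhc),
                boiling_point=float(tb),
                descriptors=desc,
            )
        )
    return records


def generate_dataset(
    chemicals: list[ChemicalRecord],
    grid: ScenarioGrid | None = None,
    cfg: SurrogateConfig | None = None,
    drop_failures: bool = True,
) -> list[ExplosionRecord]:
    """One ExplosionRecord per (chemical, scenario) cell of the factorial design.

    Cells whose surrogate evaluation fails are skipped and logged when
    ``drop_failures`` is true, re-raised otherwise.
    """
    grid = grid or standard_grid()
    cfg = cfg or SurrogateConfig()
    scenarios = enumerate_scenarios(grid)
    rng = np.random.default_rng(cfg.seed) if cfg.noise_sigma > 0 else None
    records: list[ExplosionRecord] = []
    for chem in chemicals:
        for scen in scenarios:
            try:
                d = surrogate_diameter(chem, scen, cfg, rng=rng)
            except (ValueError, ArithmeticError) as exc:
                if not drop_failures:
                    raise
                logger.warning("skipping %s x %s: %s", chem.chem_id, scen, exc)
                continue
            records.append(ExplosionRecord(chem.chem_id, scen, d))
    return records


def chemicals_to_frame(chemicals: list[ChemicalRecord]) -> pd.DataFrame:
    """Chemicals table: id, SMILES, bulk properties, then one column per descriptor."""
    rows = []
    for c in chemicals:
        row = {
            "chem_id": c.chem_id,
            "smiles": c.smiles,
            "density_kg_m3": c.density,
            "heat_of_combustion_mj_kg": c.heat_of_combustion,
            "boiling_point_c": c.boiling_point,
        }
        row.update(c.descriptors)
        rows.append(row)
    return pd.DataFrame(rows)


def dataset_to_frame(records: list[ExplosionRecord]) -> pd.DataFrame:
    """Long-format consequence table: chem_id + scenario columns + diameter_m."""
    return pd.DataFrame(
        {
            "chem_id": [r.chem_id for r in records],
            "temperature_c": [r.scenario.temperature for r in records],
            "pressure_psi": [r.scenario.pressure for r in records],
            "leak_size_in": [r.scenario.leak_size for r in records],
            "quantity_m3": [r.scenario.quantity for r in records],
            "diameter_m": [r.diameter for r in records],
        }
    )
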