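"""Neutral demographic models for the Drosophila sweep scan.

Covers a zoo of eleven models (keys A-K): two constant-size models whose
parameters are fully printed (A: Ne = 1e6; B: Ne = 2.7e6, fit to
Watterson's theta in autosomal short introns), two bottleneck models, and
seven out-of-Africa admixture variants (Africa ancestral, Europe splitting
from Africa, North America founded by admixture of the two, optionally
with growth, bottlenecks or migration). The admixture-model parameters
were inferred elsewhere from posterior distributions that are not printed
here, so those entries require a user-supplied config.

The module also encodes, as an explicit convention switch, a documented
scaling discrepancy between two published implementations of the same
admixture model: one divided the *founding* sizes of Europe and North
America by 4x the ancestral African Ne while dividing present-day sizes by
the ancestral Ne alone, producing founding bottlenecks exactly 4-fold
smaller than inferred. ``scale_for_simulator`` reproduces both conventions
so the consequences can be simulated side by side.

Config files always hold generations and diploid sizes; conversion to
simulator-scaled units happens only at the simulation boundary, to avoid
exactly this class of bug.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product

import yaml

__all__ = [
    "Epoch",
    "Population",
    "Split",
    "Admixture",
    "Migration",
    "DemographicModel",
    "ModelRegistryEntry",
    "ScaledParams",
    "registry",
    "get_model",
    "scale_for_simulator",
    "variant_grid",
    "constant_model",
    "bottleneck_model",
    "admixture_model",
]


@dataclass(frozen=True)
class Epoch:
    """Diploid size of a population from ``start_time`` generations ago
    backwards (until the next epoch or an event). ``growth_rate`` is an
    exponential per-generation rate applying forward in time within the
    epoch (0 = constant)."""

    start_time: float
    size: float
    growth_rate: float = 0.0

    def __post_init__(self):
        if self.start_time < 0:
            raise ValueError("epoch start_time must be >= 0")
        if self.size <= 0:
            raise ValueError("population sizes must be positive")


@dataclass(frozen=True)
class Population:
    name: str
    epochs: tuple[Epoch, ...]

    def __post_init__(self):
        if not self.epochs:
            raise ValueError(f"population {self.name} needs at least one epoch")
        times = [e.start_time for e in self.epochs]
        if times != sorted(times) or times[0] != 0:
            raise ValueError("epochs must start at 0 and be time-ordered")

    @property
    def present_size(self) -> float:
        return self.epochs[0].size


@dataclass(frozen=True)
class Split:
    """``child`` derives from ``parent`` at ``time`` generations ago."""

    child: str
    parent: str
    time: float


@dataclass(frozen=True)
class Admixture:
    """``child`` founded at ``time`` by ``parent_a`` (fraction ``proportion``)
    and ``parent_b`` (the rest)."""

    child: str
    parent_a: str
    parent_b: str
    proportion: float
    time: float

    def __post_init__(self):
        if not 0 <= self.proportion <= 1:
            raise ValueError("admixture proportion must lie in [0, 1]")


@dataclass(frozen=True)
class Migration:
    """Per-generation migrant fraction from ``source`` into ``dest``
    (forwards in time), active on [start_time, end_time] generations ago."""

    source: str
    dest: str
    rate: float
    start_time: float = 0.0
    end_time: float = float("inf")

    def __post_init__(self):
        if not 0 <= self.rate < 1:
            raise ValueError("migration rate must lie in [0, 1)")


@dataclass(frozen=True)
class DemographicModel:
    name: str
    populations: tuple[Population, ...]
    splits: tuple[Split, ...] = ()
    admixtures: tuple[Admixture, ...] = ()
    migrations: tuple[Migration, ...] = ()
    reference_size: float | None = None  # Ne_anc used for simulator scaling
    founding_sizes: dict = field(default_factory=dict)  # pop -> size at founding
    sample_population: str | None = None

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        self.validate()

    def pop(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def admixture_time(self) -> float | None:
        return min((a.time for a in self.admixtures), default=None)

    def validate(self) -> None:
        names = {p.name for p in self.populations}
        origin: dict[str, float] = {}  # time at which the population appears
        for s in self.splits:
            if s.time < 0:
                raise ValueError("event times must be >= 0")
            if s.child not in names or s.parent not in names:
                raise ValueError(f"split references unknown population: {s}")
            origin[s.child] = s.time
        for a in self.admixtures:
            if a.time < 0:
                raise ValueError("event times must be >= 0")
            for ref in (a.child, a.parent_a, a.parent_b):
                if ref not in names:
                    raise ValueError(f"admixture references unknown population: {a}")
            # both parents must already exist (further in the past) at a.time
            for parent in (a.parent_a, a.parent_b):
                if origin.get(parent, float("inf")) <= a.time:
                    raise ValueError(
                        f"admixture of {a.child} at t={a.time} precedes the "
                        f"origin of parent {parent} (t={origin[parent]})"
                    )
            origin[a.child] = a.time
        for m in self.migrations:
            if m.source not in names or m.dest not in names:
                raise ValueError(f"migration references unknown population: {m}")

    # -- config round-trip ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = [asdict(p) | {"epochs": [asdict(e) for e in p.epochs]}
                            for p in self.populations]
        d["splits"] = [asdict(s) for s in self.splits]
        d["admixtures"] = [asdict(a) for a in self.admixtures]
        d["migrations"] = [asdict(m) for m in self.migrations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            name=d["name"],
            populations=tuple(
                Population(p["name"], tuple(Epoch(**e) for e in p["epochs"]))
                for p in d["populations"]
            ),
            splits=tuple(Split(**s) for s in d.get("splits", [])),
            admixtures=tuple(Admixture(**a) for a in d.get("admixtures", [])),
            migrations=tuple(Migration(**m) for m in d.get("migrations", [])),
            reference_size=d.get("reference_size"),
            founding_sizes=dict(d.get("founding_sizes", {})),
            sample_population=d.get("sample_population"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DemographicModel":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)

    # -- msprime boundary -------------------------------------------------

    def to_msprime(self):
        """Convert to an ``msprime.Demography`` (times in generations)."""
        import msprime

        dem = msprime.Demography()
        for p in self.populations:
            e0 = p.epochs[0]
            dem.add_population(
                name=p.name, initial_size=e0.size, growth_rate=e0.growth_rate
            )
        events = []
        for p in self.populations:
            for e in p.epochs[1:]:
                events.append((e.start_time, "size", (p.name, e.size, e.growth_rate)))
        for s in self.splits:
            events.append((s.time, "split", s))
        for a in self.admixtures:
            events.append((a.time, "admix", a))
        for m in self.migrations:
            if m.rate > 0:
                dem.set_migration_rate(source=m.dest, dest=m.source, rate=m.rate)
                if m.end_time != float("inf"):
                    events.append((m.end_time, "mig_off", m))
        for t, kind, payload in sorted(events, key=lambda ev: ev[0]):
            if kind == "size":
                name, size, growth = payload
                dem.add_population_parameters_change(
                    time=t, population=name, initial_size=size, growth_rate=growth
                )
            elif kind == "split":
                dem.add_population_split(
                    time=t, derived=[payload.child], ancestral=payload.parent
                )
            elif kind == "admix":
                dem.add_admixture(
                    time=t,
                    derived=payload.child,
                    ancestral=[payload.parent_a, payload.parent_b],
                    proportions=[payload.proportion, 1 - payload.proportion],
                )
            elif kind == "mig_off":
                dem.add_migration_rate_change(
                    time=t, source=payload.dest, dest=payload.source, rate=0
                )
        dem.sort_events()
        return dem


# -- scaling conventions ---------------------------------------------------


@dataclass(frozen=True)
class ScaledParams:
    """Population sizes expressed as ratios of the ancestral reference Ne."""

    convention: str
    reference_size: float
    present_ratios: dict
    founding_ratios: dict


def scale_for_simulator(model: DemographicModel, convention: str = "standard") -> ScaledParams:
    """Express sizes in simulator units of the ancestral reference Ne.

    ``standard`` divides every size by Ne_anc. ``harris`` divides the
    *founding* sizes by 4*Ne_anc while present-day sizes are divided by
    Ne_anc — reproducing the published mis-scaling, whose founding
    bottlenecks come out exactly 4-fold too small.
    """
    if convention not in ("standard", "harris"):
        raise ValueError("convention must be 'standard' or 'harris'")
    ne_anc = model.reference_size
    if ne_anc is None or ne_anc <= 0:
        raise ValueError("model has no positive ancestral reference size")
    founding_div = 4 * ne_anc if convention == "harris" else ne_anc
    return ScaledParams(
        convention=convention,
        reference_size=ne_anc,
        present_ratios={p.name: p.present_size / ne_anc for p in model.populations},
        founding_ratios={k: v / founding_div for k, v in model.founding_sizes.items()},
    )


# -- model builders --------------------------------------------------------


def constant_model(name: str, ne: float) -> DemographicModel:
    return DemographicModel(
        name=name,
        populations=(Population("pop0", (Epoch(0, ne),)),),
        reference_size=ne,
        sample_population="pop0",
    )


def bottleneck_model(
    name: str, ne_present: float, ne_bottleneck: float,
    start_time: float, duration: float, ne_ancestral: float,
) -> DemographicModel:
    """Single population: ancestral size, a bottleneck of the given duration
    ending ``start_time`` generations ago, then the present size."""
    return DemographicModel(
        name=name,
        populations=(
            Population(
                "pop0",
                (
                    Epoch(0, ne_present),
                    Epoch(start_time, ne_bottleneck),
                    Epoch(start_time + duration, ne_ancestral),
                ),
            ),
        ),
        reference_size=ne_ancestral,
        founding_sizes={"pop0": ne_bottleneck},
        sample_population="pop0",
    )


def admixture_model(
    name: str,
    *,
    ne_africa: float,
    ne_europe: float,
    ne_america: float,
    ne_europe_founding: float,
    ne_america_founding: float,
    t_split_europe: float,
    t_admixture: float,
    admixture_proportion_africa: float,
    europe_growth: bool = False,
    america_growth: bool = False,
    migration: tuple[float, float] | None = None,
) -> DemographicModel:
    """Out-of-Africa admixture topology: Europe splits from Africa at
    ``t_split_europe``; North America is founded at ``t_admixture`` by an
    African fraction ``admixture_proportion_africa`` and a European rest.

    With ``*_growth`` the derived population grows exponentially from its
    founding size to the present size; otherwise the present size applies
    from founding. ``migration`` = (rate_into_america_from_africa,
    rate_into_america_from_europe), constant since admixture.
    """
    import math

    def growth_epochs(present, founding, origin_time, grow):
        if not grow or present == founding:
            return (Epoch(0, present),)
        rate = math.log(present / founding) / origin_time
        return (Epoch(0, present, growth_rate=rate),)

    pops = (
        Population("AFR", (Epoch(0, ne_africa),)),
        Population("EUR", growth_epochs(ne_europe, ne_europe_founding,
                                        t_split_europe, europe_growth)),
        Population("AMR", growth_epochs(ne_america, ne_america_founding,
                                        t_admixture, america_growth)),
    )
    migrations = ()
    if migration is not None:
        m_af, m_eu = migration
        migrations = (
            Migration("AFR", "AMR", m_af, 0.0, t_admixture),
            Migration("EUR", "AMR", m_eu, 0.0, t_admixture),
        )
    return DemographicModel(
        name=name,
        populations=pops,
        splits=(Split("EUR", "AFR", t_split_europe),),
        admixtures=(
            Admixture("AMR", "AFR", "EUR", admixture_proportion_africa, t_admixture),
        ),
        migrations=migrations,
        reference_size=ne_africa,
        founding_sizes={"EUR": ne_europe_founding, "AMR": ne_america_founding},
        sample_population="AMR",
    )


# -- registry --------------------------------------------------------------


@dataclass(frozen=True)
class ModelRegistryEntry:
    key: str
    description: str
    parameter_source: str  # "printed" | "config-required"
    builder: object = None  # zero-arg callable for printed models

    def build(self, config: dict | None = None) -> DemographicModel:
        if self.parameter_source == "printed":
            return self.builder()
        if not config:
            raise ValueError(
                f"model {self.key} ({self.description}) requires a parameter "
                "config; its inferred parameters are not printed"
            )
        return DemographicModel.from_dict(config)


_REGISTRY: list[ModelRegistryEntry] = [
    ModelRegistryEntry(
        "A", "constant Ne = 1e6", "printed",
        lambda: constant_model("A", 1_000_000),
    ),
    ModelRegistryEntry(
        "B", "constant Ne = 2.7e6 (fit to autosomal short-intron theta_W)",
        "printed", lambda: constant_model("B", 2_700_000),
    ),
    ModelRegistryEntry("C", "severe short bottleneck", "config-required"),
    ModelRegistryEntry("D", "shallow long bottleneck", "config-required"),
    ModelRegistryEntry("E", "admixture, constant EU/NA sizes (2015 implementation)",
                       "config-required"),
    ModelRegistryEntry("F", "admixture + European founding bottleneck (2015 implementation)",
                       "config-required"),
    ModelRegistryEntry("G", "admixture with growth (Duchen et al. posterior mode)",
                       "config-required"),
    ModelRegistryEntry("H", "admixture + bottleneck (Duchen et al. posterior mode)",
                       "config-required"),
    ModelRegistryEntry("I", "admixture, Harris et al. implementation (4x founding mis-scaling)",
                       "config-required"),
    ModelRegistryEntry("J", "admixture with continental migration (Arguello et al.)",
                       "config-required"),
    ModelRegistryEntry("K", "admixture with fixed NA/EU/AFR population sizes",
                       "config-required"),
]


def registry() -> list[ModelRegistryEntry]:
    """The eleven-model zoo, keyed A-K."""
    return list(_REGISTRY)


def get_model(key: str, config: dict | None = None) -> DemographicModel:
    for entry in _REGISTRY:
        if entry.key == key:
            return entry.build(config)
    raise KeyError(f"unknown model key {key!r}; valid keys are A-K")


# -- variant grids ---------------------------------------------------------

#: Printed axis values for the fixed-size variant family.
EU_CONSTANT_SIZES = (16_982, 67_608, 700_000, 2_000_000, 9_550_000)
NA_CONSTANT_SIZES = (2_500, 61_659, 1_110_000, 15_984_500, 28_800_000)
#: Printed start/end values for the growth family.
EU_GROWTH_STARTS = (16_982, 67_608)
EU_GROWTH_ENDS = (700_000, 2_000_000, 9_550_000)
NA_GROWTH_STARTS = (2_500, 61_659)
NA_GROWTH_ENDS = (1_110_000, 15_984_500, 28_800_000)


def variant_grid(
    family: str,
    base_config: dict,
    *,
    proportions: tuple[float, ...] = (),
    migration_rates: tuple[float, ...] = (),
) -> list[DemographicModel]:
    """Enumerate admixture-model variants, varying one parameter family.

    ``base_config`` supplies the held-constant parameters (posterior-mode
    values: ne_africa, t_split_europe, t_admixture,
    admixture_proportion_africa, and default sizes). Families:

    - ``constant-size``: 5 EU x 5 NA fixed present sizes = 25 models.
    - ``growth``: EU (2 starts x 3 ends) x NA (2 starts x 3 ends) = 36.
    - ``admixture-proportion``: user grid over [0, 0.9].
    - ``migration``: user grid over [0, 0.75], symmetric into America.
    """
    if not base_config:
        raise ValueError("variant_grid requires a base_config of mode parameters")
    base = dict(base_config)

    def build(name, **over):
        kwargs = dict(
            ne_africa=base["ne_africa"],
            ne_europe=base.get("ne_europe", 700_000),
            ne_america=base.get("ne_america", 1_110_000),
            ne_europe_founding=base.get("ne_europe_founding",
                                        base.get("ne_europe", 700_000)),
            ne_america_founding=base.get("ne_america_founding",
                                         base.get("ne_america", 1_110_000)),
            t_split_europe=base["t_split_europe"],
            t_admixture=base["t_admixture"],
            admixture_proportion_africa=base["admixture_proportion_africa"],
        )
        kwargs.update(over)
        return admixture_model(name, **kwargs)

    models = []
    if family == "constant-size":
        for eu, na in product(EU_CONSTANT_SIZES, NA_CONSTANT_SIZES):
            models.append(build(
                f"const_EU{eu}_NA{na}",
                ne_europe=eu, ne_america=na,
                ne_europe_founding=eu, ne_america_founding=na,
            ))
    elif family == "growth":
        eu_axis = list(product(EU_GROWTH_STARTS, EU_GROWTH_ENDS))
        na_axis = list(product(NA_GROWTH_STARTS, NA_GROWTH_ENDS))
        for (eu0, eu1), (na0, na1) in product(eu_axis, na_axis):
            models.append(build(
                f"growth_EU{eu0}-{eu1}_NA{na0}-{na1}",
                ne_europe=eu1, ne_europe_founding=eu0,
                ne_america=na1, ne_america_founding=na0,
                europe_growth=True, america_growth=True,
            ))
    elif family == "admixture-proportion":
        if not proportions:
            raise ValueError("admixture-proportion family needs a proportions grid")
        for pr in proportions:
            if not 0 <= pr <= 0.9:
                raise ValueError("admixture proportions span [0, 0.9]")
            models.append(build(f"prop_{pr:g}", admixture_proportion_africa=pr))
    elif family == "migration":
        if not migration_rates:
            raise ValueError("migration family needs a migration_rates grid")
        for m in migration_rates:
            if not 0 <= m <= 0.75:
                raise ValueError("migration rates span [0, 0.75]")
            models.append(build(f"mig_{m:g}", migration=(m, m)))
    else:
        raise ValueError(f"unknown variant family {family!r}")
    return models
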