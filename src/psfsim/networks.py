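"""Plant-soil feedback interaction (PSFI) networks and the scenario catalogue.

A plant conditions the soil of its grid cell; that conditioning sets the
growth rate of the cell's *next* occupant.  An :class:`InteractionTable`
records, for every ordered pair ``(recruit species, soil-conditioning
species)``, which of three growth-rate classes the recruit establishes with:

* ``slow``     — the conditioning species hinders the recruit,
* ``standard`` — no interaction (also the rate on never-occupied soil),
* ``fast``     — the conditioning species facilitates the recruit.

Heterospecific interactions are arranged in one of three architectures —
modular (bidirectional within discrete blocks of species), nested (a small
focal set one-directionally affects everyone else) or an intransitive ring
(each species affects the next ``g`` species around a circle) — each in a
positive or negative variant, plus a null control with no heterospecific
interactions.  Optionally every resident also hinders its own kind
(negative conspecific feedback).  A single invader species sits outside the
resident network: it facilitates itself and neither affects nor is affected
by any resident.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SLOW",
    "STANDARD",
    "FAST",
    "RATE_LABELS",
    "GrowthRates",
    "InteractionTable",
    "ScenarioSpec",
    "build_null",
    "build_modular",
    "build_nested",
    "build_ring",
    "apply_conspecific",
    "build_scenario_table",
    "enumerate_scenarios",
    "scenario_catalogue",
]

# rate-class codes used in the dense class matrix
SLOW, STANDARD, FAST = 0, 1, 2
RATE_LABELS = {SLOW: "slow", STANDARD: "standard", FAST: "fast"}
_LABEL_CODES = {v: k for k, v in RATE_LABELS.items()}


@dataclass(frozen=True)
class GrowthRates:
    """Multiplicative per-time-step growth factors for the three rate classes.

    Defaults: slow 1.49, standard 1.65, fast 1.82 (per time step).
    """

    slow: float = 1.49
    standard: float = 1.65
    fast: float = 1.82

    def __post_init__(self) -> None:
        if not (self.slow < self.standard < self.fast):
            raise ValueError(
                f"growth rates must satisfy slow < standard < fast, got "
                f"{self.slow}, {self.standard}, {self.fast}"
            )

    def as_array(self) -> np.ndarray:
        """Rate values indexed by class code (slow, standard, fast)."""
        return np.array([self.slow, self.standard, self.fast])


class ConfigurationError(ValueError):
    """Raised for inconsistent scenario or network parameters."""


@dataclass
class InteractionTable:
    """Dense growth-rate-class table over all (recruit, soil) pairs.

    Rows index the recruiting species, columns the species whose soil
    conditioning the recruit lands on.  Species ``0 .. n_resident - 1`` are
    residents, ``n_resident`` is the invader, and the extra final column is
    unconditioned (never-occupied) soil.

    The baseline table is all-standard except the invader's positive
    conspecific entry (fast); architecture builders overwrite heterospecific
    resident entries and :func:`apply_conspecific` the resident diagonal.
    """

    n_resident: int = 100
    rates: GrowthRates = field(default_factory=GrowthRates)
    classes: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_resident < 1:
            raise ConfigurationError("n_resident must be positive")
        if self.classes is None:
            n = self.n_resident
            cls = np.full((n + 1, n + 2), STANDARD, dtype=np.uint8)
            cls[n, n] = FAST  # invader facilitates itself
            self.classes = cls
        expected = (self.n_resident + 1, self.n_resident + 2)
        if self.classes.shape != expected:
            raise ConfigurationError(
                f"class matrix shape {self.classes.shape} != {expected}"
            )

    # -- indices ---------------------------------------------------------
    @property
    def invader(self) -> int:
        """Species index of the invader."""
        return self.n_resident

    @property
    def unconditioned(self) -> int:
        """Soil-state code for never-occupied soil."""
        return self.n_resident + 1

    # -- lookups ---------------------------------------------------------
    def rate_class(self, recruit: int, soil: int) -> str:
        """Rate-class label for a recruit establishing on the given soil."""
        n = self.n_resident
        if not 0 <= recruit <= n:
            raise KeyError(f"unknown recruit species {recruit}")
        if not 0 <= soil <= n + 1:
            raise KeyError(f"unknown soil state {soil}")
        return RATE_LABELS[int(self.classes[recruit, soil])]

    def rate_value(self, recruit: int, soil: int) -> float:
        """Multiplicative growth factor for the (recruit, soil) pair."""
        return float(self.values[recruit, soil])

    @property
    def values(self) -> np.ndarray:
        """Float matrix of growth factors, same shape as ``classes``."""
        return self.rates.as_array()[self.classes]

    def resident_values(self) -> np.ndarray:
        """Growth-factor matrix restricted to resident (recruit, soil) pairs."""
        n = self.n_resident
        return self.values[:n, :n]

    # -- bookkeeping ------------------------------------------------------
    def copy(self) -> "InteractionTable":
        return replace(self, classes=self.classes.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionTable):
            return NotImplemented
        return (
            self.n_resident == other.n_resident
            and self.rates == other.rates
            and np.array_equal(self.classes, other.classes)
        )

    def n_nonstandard_heterospecific(self) -> int:
        """Count of directed non-standard resident entries off the diagonal."""
        n = self.n_resident
        block = self.classes[:n, :n]
        off = ~np.eye(n, dtype=bool)
        return int(np.count_nonzero(block[off] != STANDARD))

    def affected_by_degree(self) -> np.ndarray:
        """Per resident species: number of heterospecific soils with a
        non-standard effect on it (in-degree of the effect network)."""
        n = self.n_resident
        block = self.classes[:n, :n] != STANDARD
        np.fill_diagonal(block, False)
        return block.sum(axis=1)

    # -- export -----------------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Three-column table: recruit_species, soil_species, rate_class.

        Species are 1-based in the export; the invader is labelled
        ``invader`` and unconditioned soil ``unconditioned``.
        """
        n = self.n_resident
        names = [str(i + 1) for i in range(n)] + ["invader"]
        soil_names = names + ["unconditioned"]
        recruit, soil = np.meshgrid(
            np.arange(n + 1), np.arange(n + 2), indexing="ij"
        )
        return pd.DataFrame(
            {
                "recruit_species": [names[i] for i in recruit.ravel()],
                "soil_species": [soil_names[j] for j in soil.ravel()],
                "rate_class": [
                    RATE_LABELS[c] for c in self.classes.ravel().tolist()
                ],
            }
        )

    def to_dense_frame(self) -> pd.DataFrame:
        """Dense matrix of rate-class labels (rows recruit, columns soil)."""
        n = self.n_resident
        names = [str(i + 1) for i in range(n)] + ["invader"]
        label = np.vectorize(RATE_LABELS.get)
        return pd.DataFrame(
            label(self.classes),
            index=pd.Index(names, name="recruit_species"),
            columns=names + ["unconditioned"],
        )


# ---------------------------------------------------------------------------
# architecture builders
# ---------------------------------------------------------------------------

_SIGN_CODE = {"positive": FAST, "negative": SLOW}


def _check_sign(sign: str) -> int:
    if sign not in _SIGN_CODE:
        raise ConfigurationError(
            f"sign must be 'positive' or 'negative', got {sign!r}"
        )
    return _SIGN_CODE[sign]


def build_null(n_species: int = 100, rates: GrowthRates | None = None) -> InteractionTable:
    """Control table with no heterospecific interactions at all."""
    return InteractionTable(n_species, rates or GrowthRates())


def build_modular(
    n_species: int,
    group_size: int,
    sign: str,
    rates: GrowthRates | None = None,
) -> InteractionTable:
    """Bidirectional interactions inside contiguous modules of ``group_size``.

    Every ordered heterospecific pair within a module is set to the sign's
    rate class; cross-module and conspecific entries stay standard.  Each
    species is therefore affected by ``group_size - 1`` others.
    """
    code = _check_sign(sign)
    if n_species % group_size != 0:
        raise ConfigurationError(
            f"group_size {group_size} does not divide n_species {n_species}"
        )
    table = build_null(n_species, rates)
    for start in range(0, n_species, group_size):
        block = slice(start, start + group_size)
        table.classes[block, block] = code
        table.classes[block, block][np.eye(group_size, dtype=bool)] = STANDARD
    return table


def build_nested(
    n_species: int,
    group_size: int,
    sign: str,
    rates: GrowthRates | None = None,
) -> InteractionTable:
    """A focal set of ``group_size`` highly interactive species one-directionally
    affects every other species (focal members included); non-focal species
    affect nobody.

    Non-focal species are affected by ``group_size`` soils, focal species by
    ``group_size - 1`` (not their own).  The focal block is canonically
    species ``1 .. group_size``; species labels are exchangeable, so any other
    placement is a relabelling.
    """
    code = _check_sign(sign)
    if group_size >= n_species:
        raise ConfigurationError(
            f"group_size {group_size} must be smaller than n_species {n_species}"
        )
    table = build_null(n_species, rates)
    table.classes[:n_species, :group_size] = code
    diag = np.arange(group_size)
    table.classes[diag, diag] = STANDARD
    return table


def build_ring(
    n_species: int,
    group_size: int,
    sign: str,
    rates: GrowthRates | None = None,
) -> InteractionTable:
    """Intransitive ring: species ``j`` affects species ``j+1 .. j+group_size``
    (indices wrapping), so every species has in- and out-degree ``group_size``
    and no species is a global winner."""
    code = _check_sign(sign)
    if group_size >= n_species:
        raise ConfigurationError(
            f"group_size {group_size} must be smaller than n_species {n_species}"
        )
    table = build_null(n_species, rates)
    j = np.arange(n_species)
    for offset in range(1, group_size + 1):
        table.classes[(j + offset) % n_species, j] = code
    return table


def apply_conspecific(table: InteractionTable) -> InteractionTable:
    """Return a copy with negative conspecific feedback: every resident grows
    slow on soil conditioned by its own species.  The invader's positive
    conspecific entry is untouched.  Idempotent."""
    out = table.copy()
    n = out.n_resident
    diag = np.arange(n)
    out.classes[diag, diag] = SLOW
    return out


# ---------------------------------------------------------------------------
# scenario catalogue
# ---------------------------------------------------------------------------

_ARCH_TOKEN = {"modular": "Mod", "nested": "Nest", "ring": "Ring"}
_TOKEN_ARCH = {v: k for k, v in _ARCH_TOKEN.items()}
_SIGN_TOKEN = {"positive": "Pos", "negative": "Neg"}
_TOKEN_SIGN = {v: k for k, v in _SIGN_TOKEN.items()}

GROUP_SIZES = (5, 10, 20)
ARCHITECTURES = ("modular", "ring", "nested")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named point in the 38-scenario PSFI design.

    ``invasion`` is not part of the scenario name; the experiment layer
    crosses every scenario with and without an invasion event.
    """

    architecture: str = "null"
    sign: str = "none"
    group_size: int | None = None
    conspecific_negative: bool = False
    invasion: bool = False

    def __post_init__(self) -> None:
        if self.architecture == "null":
            if self.sign != "none" or self.group_size is not None:
                raise ConfigurationError(
                    "null architecture takes no sign and no group size"
                )
        else:
            if self.architecture not in _ARCH_TOKEN:
                raise ConfigurationError(
                    f"unknown architecture {self.architecture!r}"
                )
            if self.sign not in _SIGN_TOKEN:
                raise ConfigurationError(
                    f"architecture {self.architecture} needs a positive or "
                    f"negative sign, got {self.sign!r}"
                )
            if self.group_size is None or self.group_size < 2:
                raise ConfigurationError("group_size must be an integer >= 2")

    @property
    def name(self) -> str:
        """Catalogue name, e.g. ``Neg.Nest.20.NC`` or ``Null``."""
        if self.architecture == "null":
            base = "Null"
        else:
            base = (
                f"{_SIGN_TOKEN[self.sign]}.{_ARCH_TOKEN[self.architecture]}"
                f".{self.group_size}"
            )
        return base + (".NC" if self.conspecific_negative else "")

    @classmethod
    def from_name(cls, name: str, invasion: bool = False) -> "ScenarioSpec":
        """Parse a catalogue name back into its fields (inverse of ``name``)."""
        parts = name.split(".")
        conspecific = False
        if parts and parts[-1] == "NC":
            conspecific = True
            parts = parts[:-1]
        if parts == ["Null"]:
            return cls(conspecific_negative=conspecific, invasion=invasion)
        if len(parts) == 3 and parts[0] in _TOKEN_SIGN and parts[1] in _TOKEN_ARCH:
            return cls(
                architecture=_TOKEN_ARCH[parts[1]],
                sign=_TOKEN_SIGN[parts[0]],
                group_size=int(parts[2]),
                conspecific_negative=conspecific,
                invasion=invasion,
            )
        raise ConfigurationError(f"cannot parse scenario name {name!r}")

    def with_invasion(self, invasion: bool = True) -> "ScenarioSpec":
        return replace(self, invasion=invasion)


def build_scenario_table(
    scenario: ScenarioSpec,
    n_species: int = 100,
    rates: GrowthRates | None = None,
) -> InteractionTable:
    """Materialise the interaction table for a scenario."""
    if scenario.architecture == "null":
        table = build_null(n_species, rates)
    else:
        builder = {
            "modular": build_modular,
            "nested": build_nested,
            "ring": build_ring,
        }[scenario.architecture]
        table = builder(n_species, scenario.group_size, scenario.sign, rates)
    if scenario.conspecific_negative:
        table = apply_conspecific(table)
    return table


def enumerate_scenarios() -> list[ScenarioSpec]:
    """All 38 scenarios of the design in a stable catalogue order.

    19 heterospecific scenarios (null + 3 architectures x 3 group sizes x
    2 signs), each with and without negative conspecific feedback.
    """
    bases: list[ScenarioSpec] = [ScenarioSpec()]
    for arch, sign, g in itertools.product(
        ARCHITECTURES, ("positive", "negative"), GROUP_SIZES
    ):
        bases.append(ScenarioSpec(architecture=arch, sign=sign, group_size=g))
    out: list[ScenarioSpec] = []
    for base in bases:
        out.append(base)
        out.append(replace(base, conspecific_negative=True))
    return out


def scenario_catalogue() -> pd.DataFrame:
    """The scenario design as a tidy table (one row per scenario)."""
    rows = []
    for s in enumerate_scenarios():
        rows.append(
            {
                "name": s.name,
                "heterospecific_sign": s.sign,
                "architecture": s.architecture,
                "group_size": s.group_size,
                "conspecific": "negative" if s.conspecific_negative else "none",
            }
        )
    return pd.DataFrame(rows)
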