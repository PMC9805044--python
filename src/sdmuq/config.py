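"""Experiment configuration: schema, defaults, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from .forcing import EsmStyle, default_styles
from .grids import GridSpec
from .operating_model import ArchetypeSpec, ResponseCurve, default_archetypes
from .sdm import DEFAULT_EXCLUSIONS, DEFAULT_ROSTER

__all__ = ["ExperimentConfig"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run the full simulation experiment once."""

    grid: GridSpec = field(default_factory=GridSpec)
    styles: tuple[EsmStyle, ...] = field(
        default_factory=lambda: tuple(default_styles()))
    archetypes: tuple[ArchetypeSpec, ...] = field(
        default_factory=lambda: tuple(default_archetypes().values()))
    roster: tuple[tuple[str, str], ...] = DEFAULT_ROSTER
    exclusions: frozenset[str] = DEFAULT_EXCLUSIONS
    include_temperature_only: bool = True
    n_per_year: int = 500
    train_years: tuple[int, int] = (1985, 2010)
    test_years: tuple[int, int] = (2011, 2100)
    smooth_window: int = 11
    master_seed: int = 0

    def __post_init__(self):
        from .sampling import SDM_COVARIATES

        names = [a.name for a in self.archetypes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate archetype names")
        unknown = [n for n in names if n not in SDM_COVARIATES]
        if unknown:
            raise ValueError(f"unknown archetype name(s): {', '.join(unknown)}")
        esms = [s.esm_id for s in self.styles]
        if len(set(esms)) != len(esms):
            raise ValueError("duplicate ESM ids")
        for sdm_id in self.exclusions:
            fam, _, param = sdm_id.partition("_")
            if not fam or not param:
                raise ValueError(f"malformed exclusion id {sdm_id!r}")
        if self.train_years[0] < self.grid.year_start or \
                self.test_years[1] > self.grid.year_end:
            raise ValueError("train/test years outside the grid's year range")

    @property
    def esm_ids(self) -> list[str]:
        return [s.esm_id for s in self.styles]

    @property
    def archetype_names(self) -> list[str]:
        return [a.name for a in self.archetypes]

    def archetype(self, name: str) -> ArchetypeSpec:
        for a in self.archetypes:
            if a.name == name:
                return a
        raise KeyError(f"unknown archetype {name!r}")

    def style(self, esm_id: str) -> EsmStyle:
        for s in self.styles:
            if s.esm_id == esm_id:
                return s
        raise KeyError(f"unknown ESM {esm_id!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "grid": asdict(self.grid),
            "esm_styles": [asdict(s) for s in self.styles],
            "archetypes": [asdict(a) for a in self.archetypes],
            "roster": [list(rp) for rp in self.roster],
            "exclusions": sorted(self.exclusions),
            "include_temperature_only": self.include_temperature_only,
            "n_per_year": self.n_per_year,
            "train_years": list(self.train_years),
            "test_years": list(self.test_years),
            "smooth_window": self.smooth_window,
            "master_seed": self.master_seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        base = cls()
        grid = GridSpec(**d["grid"]) if "grid" in d else base.grid
        styles = tuple(EsmStyle(**s) for s in d["esm_styles"]) \
            if "esm_styles" in d else base.styles
        if "archetypes" in d:
            archetypes = []
            for a in d["archetypes"]:
                a = dict(a)
                a["curves"] = tuple(ResponseCurve(**c) for c in a["curves"])
                archetypes.append(ArchetypeSpec(**a))
            archetypes = tuple(archetypes)
        else:
            archetypes = base.archetypes
        return cls(
            grid=grid, styles=styles, archetypes=archetypes,
            roster=tuple(tuple(rp) for rp in d.get("roster", base.roster)),
            exclusions=frozenset(d.get("exclusions", base.exclusions)),
            include_temperature_only=d.get(
                "include_temperature_only", base.include_temperature_only),
            n_per_year=d.get("n_per_year", base.n_per_year),
            train_years=tuple(d.get("train_years", base.train_years)),
            test_years=tuple(d.get("test_years", base.test_years)),
            smooth_window=d.get("smooth_window", base.smooth_window),
            master_seed=d.get("master_seed", base.master_seed),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        """Stable hash of the full configuration (for stage memoization)."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]

    def with_seed(self, master_seed: int) -> "ExperimentConfig":
        return replace(self, master_seed=int(master_seed))
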