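"""Catalog of immune cell types, polarization states, driving cytokines and markers.

The registry anchors both training (which treatments count as "driving" a
state, which marker genes gate the fully-polarized filter) and prediction
(which state models apply to a cell of a given type).  It is a plain TSV
table so users can extend or replace it.
"""
from __future__ import annotations

import csv
import unicodedata
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "PACKAGED_DEFAULT",
    "PolarizationState",
    "Registry",
    "RegistryError",
    "load_registry",
    "write_registry",
    "states_for",
    "normalize_cytokine",
]

PACKAGED_DEFAULT = "packaged-default"

STATE_LETTERS = "abcdef"

_REQUIRED_COLUMNS = ("state_id", "cell_type", "driving_cytokines")


class RegistryError(ValueError):
    """Malformed or inconsistent polarization-state registry."""


def normalize_cytokine(name: str) -> str:
    """Normalize a cytokine name for matching.

    Unicode NFKC normalization, case folding, and unification of the
    various dash characters that show up in dataset metadata (so
    "IFN-β", "ifn-β" and "IFN‐β" all compare equal).
    """
    s = unicodedata.normalize("NFKC", name).strip().casefold()
    for dash in ("‐", "‑", "‒", "–", "—", "−"):
        s = s.replace(dash, "-")
    return s


def _normalize_cell_type(name: str) -> str:
    return unicodedata.normalize("NFKC", name).strip().casefold()


@dataclass(frozen=True)
class PolarizationState:
    """One registry entry: a cytokine-driven polarization state of one cell type."""

    state_id: str
    cell_type: str
    driving_cytokines: tuple[str, ...]
    marker_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "-" not in self.state_id:
            raise RegistryError(
                f"state_id {self.state_id!r} is not of the form '<abbrev>-<letter>'"
            )
        if self.letter not in STATE_LETTERS:
            raise RegistryError(
                f"state_id {self.state_id!r} must end in a letter a-f, got {self.letter!r}"
            )
        if not self.driving_cytokines:
            raise RegistryError(f"state {self.state_id!r} has no driving cytokines")
        if not self.cell_type.strip():
            raise RegistryError(f"state {self.state_id!r} has empty cell_type")

    @property
    def letter(self) -> str:
        return self.state_id.rsplit("-", 1)[1]

    def drives(self, treatment: str) -> bool:
        """True if *treatment* names one of this state's driving cytokines."""
        t = normalize_cytokine(treatment)
        return any(normalize_cytokine(c) == t for c in self.driving_cytokines)


@dataclass
class Registry:
    """Validated collection of polarization states across cell types."""

    states: list[PolarizationState]
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.states:
            if s.state_id in seen:
                raise RegistryError(f"duplicate state_id {s.state_id!r}")
            seen.add(s.state_id)
        if not self.cell_types:
            # preserve first-appearance order
            self.cell_types = list(dict.fromkeys(s.cell_type for s in self.states))
        known = {_normalize_cell_type(c) for c in self.cell_types}
        for s in self.states:
            if _normalize_cell_type(s.cell_type) not in known:
                raise RegistryError(
                    f"state {s.state_id!r} has cell_type {s.cell_type!r} "
                    "missing from cell_types"
                )

    def __len__(self) -> int:
        return len(self.states)

    def state(self, state_id: str) -> PolarizationState:
        for s in self.states:
            if s.state_id == state_id:
                return s
        raise KeyError(state_id)

    @property
    def state_ids(self) -> list[str]:
        return [s.state_id for s in self.states]


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(x.strip() for x in cell.split(";") if x.strip())


def load_registry(path: str | Path = PACKAGED_DEFAULT) -> Registry:
    """Load a registry from a TSV file, or the packaged default catalog.

    The file must be UTF-8 tab-delimited with columns ``state_id``,
    ``cell_type``, ``driving_cytokines`` and optionally ``marker_genes``;
    list-valued columns are ``;``-joined.
    """
    if path == PACKAGED_DEFAULT:
        ref = resources.files("polarassess") / "data" / "default_registry.tsv"
        with resources.as_file(ref) as p:
            return _parse_registry(Path(p))
    return _parse_registry(Path(path))


def _parse_registry(path: Path) -> Registry:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise RegistryError(f"{path}: missing required column(s) {missing}")
        states: list[PolarizationState] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                sid = (row["state_id"] or "").strip()
                ct = (row["cell_type"] or "").strip()
                if not sid or not ct or row.get("driving_cytokines") is None:
                    raise RegistryError("incomplete row")
                state = PolarizationState(
                    state_id=sid,
                    cell_type=ct,
                    driving_cytokines=_split_list(row["driving_cytokines"]),
                    marker_genes=_split_list(row.get("marker_genes") or ""),
                )
            except RegistryError as exc:
                raise RegistryError(f"{path}: line {lineno}: {exc}") from exc
            if state.state_id in seen:
                raise RegistryError(
                    f"{path}: line {lineno}: duplicate state_id {state.state_id!r}"
                )
            seen.add(state.state_id)
            states.append(state)
    if not states:
        warnings.warn(f"registry {path} contains no states", stacklevel=2)
    return Registry(states=states)


def write_registry(registry: Registry, path: str | Path) -> None:
    """Write a registry back to TSV (inverse of :func:`load_registry`)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["state_id", "cell_type", "driving_cytokines", "marker_genes"])
        for s in registry.states:
            writer.writerow(
                [s.state_id, s.cell_type, ";".join(s.driving_cytokines), ";".join(s.marker_genes)]
            )


def states_for(registry: Registry, cell_type: str) -> list[PolarizationState]:
    """All states of *cell_type* (case-insensitive), preserving registry order.

    Unknown cell types are a soft miss: returns an empty list with a warning.
    """
    key = _normalize_cell_type(cell_type)
    hits = [s for s in registry.states if _normalize_cell_type(s.cell_type) == key]
    if not hits and key not in {_normalize_cell_type(c) for c in registry.cell_types}:
        warnings.warn(f"cell type {cell_type!r} not present in registry", stacklevel=2)
    return hits
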