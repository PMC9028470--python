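"""Trait schema: metadata describing each scorable skeletal trait.

A trait is an ordinal morphoscopic variable with two or three stages
(e.g. suture closure scored 0/1, vertebral degeneration scored 0/1/2).
Bilateral traits are observed on both sides of the skeleton and collapse
to a single column during preprocessing (left preferred, right as
surrogate). The ``block`` label groups traits by anatomical region and
drives the named trait presets used in evaluation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import yaml

#: Recognised anatomical blocks.
BLOCKS = (
    "sutures",
    "axial",
    "appendicular",
    "clavicle",
    "first_rib",
    "pubic_symphysis",
    "sacroiliac",
    "acetabulum",
)


class SchemaError(ValueError):
    """Raised when a trait schema is internally inconsistent."""


@dataclass(frozen=True)
class Trait:
    """Metadata for one unique skeletal trait.

    Parameters
    ----------
    trait_id : str
        Unique identifier (CSV column name, without side suffix).
    n_stages : int
        Number of ordinal stages, 2 or 3. Stage codes are 0-based.
    bilateral : bool
        Whether the trait is scored on both body sides.
    block : str
        Anatomical block label, one of :data:`BLOCKS`.
    """

    trait_id: str
    n_stages: int
    bilateral: bool
    block: str

    def __post_init__(self) -> None:
        if self.n_stages not in (2, 3):
            raise SchemaError(
                f"trait {self.trait_id!r}: n_stages must be 2 or 3, "
                f"got {self.n_stages}"
            )
        if self.block not in BLOCKS:
            raise SchemaError(
                f"trait {self.trait_id!r}: unknown block {self.block!r}; "
                f"valid blocks: {', '.join(BLOCKS)}"
            )


class TraitSchema:
    """Ordered collection of unique :class:`Trait` definitions."""

    def __init__(self, traits: Iterable[Trait]):
        traits = list(traits)
        ids = [t.trait_id for t in traits]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate trait ids: {sorted(dupes)}")
        self._traits: dict[str, Trait] = {t.trait_id: t for t in traits}

    def __len__(self) -> int:
        return len(self._traits)

    def __iter__(self) -> Iterator[Trait]:
        return iter(self._traits.values())

    def __contains__(self, trait_id: str) -> bool:
        return trait_id in self._traits

    def __getitem__(self, trait_id: str) -> Trait:
        try:
            return self._traits[trait_id]
        except KeyError:
            raise KeyError(f"trait {trait_id!r} not in schema") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitSchema):
            return NotImplemented
        return list(self) == list(other)

    @property
    def trait_ids(self) -> list[str]:
        return list(self._traits)

    @property
    def n_raw_columns(self) -> int:
        """Number of side-expanded observation columns (bilateral count twice)."""
        return sum(2 if t.bilateral else 1 for t in self)

    def subset(self, trait_ids: Iterable[str]) -> "TraitSchema":
        return TraitSchema(self[t] for t in trait_ids)

    def blocks(self) -> dict[str, list[str]]:
        """Trait ids grouped by anatomical block."""
        out: dict[str, list[str]] = {}
        for t in self:
            out.setdefault(t.block, []).append(t.trait_id)
        return out

    def resolve_preset(self, name: str) -> list[str]:
        """Resolve a named trait preset to a list of trait ids.

        Valid presets are the anatomical block names plus ``degenerative``
        (axial + appendicular), ``standard`` (clavicle, first rib, pubic
        symphysis, sacroiliac, acetabulum) and ``all``.
        """
        blocks = self.blocks()
        presets = dict(blocks)
        presets["degenerative"] = blocks.get("axial", []) + blocks.get(
            "appendicular", []
        )
        presets["standard"] = [
            tid
            for b in ("clavicle", "first_rib", "pubic_symphysis", "sacroiliac",
                      "acetabulum")
            for tid in blocks.get(b, [])
        ]
        presets["all"] = self.trait_ids
        if name not in presets:
            raise SchemaError(
                f"unknown trait preset {name!r}; valid presets: "
                f"{', '.join(sorted(presets))}"
            )
        return presets[name]

    # ---- persistence ------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        records = [
            {
                "trait_id": t.trait_id,
                "n_stages": t.n_stages,
                "bilateral": t.bilateral,
                "block": t.block,
            }
            for t in self
        ]
        Path(path).write_text(yaml.safe_dump(records, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitSchema":
        records = yaml.safe_load(Path(path).read_text())
        if not isinstance(records, list):
            raise SchemaError(f"{path}: expected a list of trait records")
        return cls(
            Trait(
                trait_id=str(r["trait_id"]),
                n_stages=int(r["n_stages"]),
                bilateral=bool(r["bilateral"]),
                block=str(r["block"]),
            )
            for r in records
        )
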