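"""Substrate linkage-target ontology for CAZy families and CUPP groups.

CAZy families group carbohydrate-active enzymes by sequence similarity, but a
single family can attack several different bonds in feed polysaccharides.
This module provides the "nuance" layer that maps a family (optionally
sharpened by a CUPP sub-family group) onto one or more *linkage targets*:
hierarchical substrate labels of the form

    major polysaccharide :: polysaccharide branch :: specific target

e.g. ``Xylan::Xylan - Backbone::β-1,4::Xyl`` for an endo-xylanase attacking
the xylose backbone, or ``Pectin::Homogalacturonan::Methylation`` for a
pectin methylesterase.  A curated default mapping is packaged; users supply
their own TSV to override it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageTarget",
    "TargetMapping",
    "MappingSchemaError",
    "MappingValidationError",
    "load_mapping",
    "default_mapping",
]

#: Sentinel label for an unspecified branch or specific target.
UNDEFINED = "Undefined"

_SEP = "::"


class MappingSchemaError(ValueError):
    """A mapping table is missing a required column."""


class MappingValidationError(ValueError):
    """A mapping table is structurally invalid (duplicates, bad weights)."""


def _normalise_label(label: str) -> str:
    """Collapse whitespace around the ``::`` separator and trim the label."""
    parts = [p.strip() for p in str(label).split(_SEP)]
    return _SEP.join(parts).strip()


@dataclass(frozen=True, order=True)
class LinkageTarget:
    """One substrate linkage target: the bond or substitution an enzyme attacks.

    Parameters
    ----------
    major_polysaccharide:
        Controlled-vocabulary polysaccharide label (``Pectin``, ``Xylan``,
        ``Starch``, ...).
    branch:
        Sub-structure within the polysaccharide (``Arabinogalactan``,
        ``Xylan - Backbone``, ...) or ``"Undefined"``.
    specific_target:
        Linkage or substitution label (``β-1,4::Xyl``, ``Acetylation``,
        ``Ferulic acid``, ...) or ``"Undefined"``.  Whitespace around an
        internal ``::`` is canonicalised away so that formatting and parsing
        round-trip.
    """

    major_polysaccharide: str
    branch: str = UNDEFINED
    specific_target: str = UNDEFINED

    def __post_init__(self) -> None:
        for name in ("major_polysaccharide", "branch", "specific_target"):
            value = _normalise_label(getattr(self, name))
            if not value:
                raise ValueError(f"LinkageTarget field {name!r} must be non-empty")
            object.__setattr__(self, name, value)

    def canonical(self) -> str:
        """Canonical string form ``major::branch::specific``."""
        return _SEP.join(
            (self.major_polysaccharide, self.branch, self.specific_target)
        )

    @classmethod
    def parse(cls, text: str) -> "LinkageTarget":
        """Parse a canonical string back into a target.

        Only the first two separators delimit fields; any further ``::``
        belongs to the specific target (e.g. ``...::α-1,4::Glc``).
        """
        parts = text.split(_SEP, 2)
        if len(parts) != 3 or not all(p.strip() for p in parts):
            raise ValueError(f"not a canonical linkage-target string: {text!r}")
        return cls(*parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


def canonical_name(target: LinkageTarget) -> str:
    """Canonical ``major::branch::specific`` name of *target*."""
    return target.canonical()


_REQUIRED_COLUMNS = ("family", "cupp_group", "major", "branch", "specific")
_WEIGHT_TOL = 1e-9


@dataclass
class TargetMapping:
    """Validated (family, cupp_group) → weighted linkage-target mapping.

    Keys with a blank ``cupp_group`` are family-level rules; a key with a
    group set is more specific and shadows the family rule during
    resolution.  Per-key weights are positive and sum to 1.
    """

    rules: Mapping[tuple[str, str], tuple[tuple[LinkageTarget, float], ...]]
    _warned: set = field(default_factory=set, repr=False)

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def targets(self) -> list[LinkageTarget]:
        """Sorted list of the distinct targets referenced by any rule."""
        seen = {t for rule in self.rules.values() for t, _ in rule}
        return sorted(seen)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def families(self) -> list[str]:
        return sorted({fam for fam, _ in self.rules})

    def resolve(
        self, family: str, cupp_group: Optional[str] = None
    ) -> list[LinkageTarget]:
        """Targets for the most specific rule available, or ``[]`` if unknown."""
        return [t for t, _ in self.resolve_weighted(family, cupp_group)]

    def resolve_weighted(
        self, family: str, cupp_group: Optional[str] = None
    ) -> tuple[tuple[LinkageTarget, float], ...]:
        """(target, weight) pairs for ``(family, cupp_group)``.

        Falls back to the family-level rule when the group rule is absent;
        unknown families yield an empty tuple (logged once per key).
        """
        family = str(family).strip()
        group = "" if cupp_group is None else str(cupp_group).strip()
        if group and (family, group) in self.rules:
            return self.rules[(family, group)]
        if (family, "") in self.rules:
            return self.rules[(family, "")]
        key = (family, group)
        if key not in self._warned:
            self._warned.add(key)
            logger.info("no linkage target for CAZy key %s; returning none", key)
        return ()


def _build_rules(df: pd.DataFrame, source: str) -> TargetMapping:
    dup_cols = ["family", "cupp_group", "major", "branch", "specific"]
    dups = df[df.duplicated(dup_cols, keep=False)]
    if not dups.empty:
        first = dups.iloc[0]
        raise MappingValidationError(
            f"{source}: duplicate mapping row for key "
            f"({first['family']!r}, {first['cupp_group']!r}) -> "
            f"{first['major']}::{first['branch']}::{first['specific']}"
        )

    rules: dict[tuple[str, str], tuple[tuple[LinkageTarget, float], ...]] = {}
    for (family, group), sub in df.groupby(["family", "cupp_group"], sort=True):
        targets = [
            LinkageTarget(row.major, row.branch, row.specific)
            for row in sub.itertuples()
        ]
        has_weight = sub["weight"].notna()
        if has_weight.any() and not has_weight.all():
            raise MappingValidationError(
                f"{source}: key ({family!r}, {group!r}) mixes weighted and "
                "unweighted rows"
            )
        if has_weight.all():
            weights = sub["weight"].astype(float).tolist()
            if any(w <= 0 for w in weights):
                raise MappingValidationError(
                    f"{source}: non-positive weight for key ({family!r}, {group!r})"
                )
            total = sum(weights)
            if abs(total - 1.0) > _WEIGHT_TOL:
                raise MappingValidationError(
                    f"{source}: weights for key ({family!r}, {group!r}) sum to "
                    f"{total!r}, expected 1"
                )
        else:
            weights = [1.0 / len(targets)] * len(targets)
        rules[(str(family), str(group))] = tuple(zip(targets, weights))
    return TargetMapping(rules)


def load_mapping(path: Union[str, Path]) -> TargetMapping:
    """Load and validate a linkage-target mapping TSV.

    The table is UTF-8, tab-separated, ``#`` comment lines allowed, with
    columns ``family  cupp_group  major  branch  specific  weight`` (weight
    optional; blank ``cupp_group`` marks a family-level rule).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MappingSchemaError(
            f"{path}: mapping table is missing column(s) {', '.join(missing)}"
        )
    if "weight" not in df.columns:
        df["weight"] = pd.NA
    if df.empty:
        return TargetMapping({})
    for col in ("family", "major", "branch", "specific"):
        blank = df[col].isna() | (df[col].str.strip() == "")
        if blank.any():
            raise MappingValidationError(
                f"{path}: blank {col!r} in row {int(df.index[blank][0]) + 2}"
            )
    df = df.assign(
        family=df["family"].str.strip(),
        cupp_group=df["cupp_group"].fillna("").str.strip(),
        weight=pd.to_numeric(df["weight"], errors="coerce"),
    )
    mapping = _build_rules(df, str(path))
    logger.info(
        "loaded mapping %s: %d rules, %d distinct linkage targets",
        path.name, len(mapping), mapping.n_targets,
    )
    return mapping


def default_mapping() -> TargetMapping:
    """The curated linkage-target mapping packaged with :mod:`cazlink`."""
    with resources.as_file(
        resources.files("cazlink.data").joinpath("linkage_targets.tsv")
    ) as path:
        return load_mapping(path)
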