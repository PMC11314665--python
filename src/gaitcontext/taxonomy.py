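"""Object-class taxonomy with role queries.

The built-in taxonomy covers the 18 classes (in 4 categories) used to
contextualize free-living gait: room/environment context, fall-risk
hazards, and privacy-sensitive classes that the anonymization stage blurs.
Each class carries one or more *roles*:

* ``context`` — informs the environment the wearer moves through;
* ``fall_risk`` — a potential extrinsic hazard (trip/slip);
* ``privacy`` — region must be obscured before anyone views the video.

A class may hold several roles: a detected person is simultaneously a
navigable obstacle (context) and a privacy region to blur.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

VALID_ROLES = frozenset({"context", "fall_risk", "privacy"})


@dataclass(frozen=True)
class ClassDef:
    name: str
    category: int
    roles: frozenset[str]
    rationale: str = ""

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("class name must be non-empty")
        if not self.roles:
            raise ValueError(f"class {self.name!r} has no roles")
        unknown = set(self.roles) - VALID_ROLES
        if unknown:
            raise ValueError(f"class {self.name!r}: unknown roles {sorted(unknown)}")
        if not 1 <= self.category:
            raise ValueError(f"class {self.name!r}: category must be positive")


@dataclass(frozen=True)
class Taxonomy:
    classes: tuple[ClassDef, ...]
    _index: dict[str, ClassDef] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, ClassDef] = {}
        for cd in self.classes:
            key = cd.name.strip().lower()
            if key in index:
                raise ValueError(f"duplicate class name {cd.name!r}")
            index[key] = cd
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._index

    def __getitem__(self, name: str) -> ClassDef:
        try:
            return self._index[name.strip().lower()]
        except KeyError:
            raise KeyError(f"class {name!r} not in taxonomy") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(cd.name for cd in self.classes)

    @property
    def categories(self) -> tuple[int, ...]:
        return tuple(sorted({cd.category for cd in self.classes}))

    def class_id(self, name: str) -> int:
        """Positional index of a class (used by YOLO-style annotation files)."""
        cd = self[name]
        return self.classes.index(cd)

    def with_role(self, role: str) -> tuple[str, ...]:
        if role not in VALID_ROLES:
            raise ValueError(f"unknown role {role!r}")
        return tuple(cd.name for cd in self.classes if role in cd.roles)


def _parse_roles(token: str) -> frozenset[str]:
    roles = frozenset(r.strip().lower() for r in token.replace("+", ",").split(",") if r.strip())
    return roles


def load_taxonomy(source: Union[str, Path] = "builtin") -> Taxonomy:
    """Load a taxonomy from the packaged table or a user TSV/CSV file.

    The file must be a delimited table (tab or comma) with columns
    ``name``, ``category``, ``roles`` and optionally ``rationale``;
    ``roles`` is a comma- or plus-separated subset of
    ``{context, fall_risk, privacy}``.
    """
    if isinstance(source, str) and source == "builtin":
        ref = resources.files("gaitcontext").joinpath("data/taxonomy.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty taxonomy file: {source}")
    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=delimiter)
    required = {"name", "category", "roles"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(f"taxonomy file must have columns {sorted(required)}")
    classes = []
    for row in reader:
        classes.append(
            ClassDef(
                name=row["name"].strip(),
                category=int(row["category"]),
                roles=_parse_roles(row["roles"]),
                rationale=(row.get("rationale") or "").strip(),
            )
        )
    return Taxonomy(tuple(classes))


def write_taxonomy(taxonomy: Taxonomy, path: Union[str, Path]) -> None:
    """Write a taxonomy as a TSV that :func:`load_taxonomy` reads back."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["name", "category", "roles", "rationale"])
        for cd in taxonomy.classes:
            writer.writerow(
                [cd.name, cd.category, ",".join(sorted(cd.roles)), cd.rationale]
            )


def is_privacy_class(taxonomy: Taxonomy, name: str) -> bool:
    """True iff detections of this class must be blurred."""
    return "privacy" in taxonomy[name].roles


def is_hazard_class(taxonomy: Taxonomy, name: str) -> bool:
    """True iff this class is a potential extrinsic fall-risk hazard."""
    return "fall_risk" in taxonomy[name].roles


def is_context_class(taxonomy: Taxonomy, name: str) -> bool:
    return "context" in taxonomy[name].roles


def roles_of(taxonomy: Taxonomy, names: Iterable[str]) -> dict[str, frozenset[str]]:
    return {n: taxonomy[n].roles for n in names}
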