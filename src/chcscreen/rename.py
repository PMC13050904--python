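"""Gene-name harmonization between annotation releases.

Receptor gene names changed between the old and new genome annotations
(paralog suffixes like ``HsOr307.1`` collapsed to plain numbers, one gene
recovered from an accession id, and one pair of names exchanged).  The map
is applied atomically over a whole vocabulary in a single pass — never
entry-by-entry — because some new names reuse old names (``HsOr257.2`` →
``HsOr258`` while the old ``HsOr258`` becomes ``HsOr386``), and a swap pair
must exchange simultaneously.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class RenameEntry:
    old_name: str
    new_name: str
    swap: bool = False


@dataclass(frozen=True)
class RenameMap:
    """Ordered old→new rename entries, swaps flagged."""

    entries: tuple[RenameEntry, ...]

    def __post_init__(self) -> None:
        olds = [e.old_name for e in self.entries]
        if len(olds) != len(set(olds)):
            raise ValueError("rename map lists an old name twice")

    def as_dict(self) -> dict[str, str]:
        return {e.old_name: e.new_name for e in self.entries}

    def apply(self, names: Sequence[str]) -> list[str]:
        """Rename every listed name in one atomic pass.

        Unlisted names pass through unchanged and order is preserved.
        Raises ``ValueError`` if the renamed vocabulary would contain a
        duplicate (two distinct inputs mapping to the same output).
        """
        mapping = self.as_dict()
        out = [mapping.get(n, n) for n in names]
        seen: dict[str, str] = {}
        for src, dst in zip(names, out):
            if dst in seen and seen[dst] != src:
                raise ValueError(
                    f"rename would create duplicate name {dst!r} "
                    f"(from {seen[dst]!r} and {src!r})"
                )
            seen[dst] = src
        return out


def apply_rename_map(names: Sequence[str], rename_map: RenameMap) -> list[str]:
    """Functional alias for :meth:`RenameMap.apply`."""
    return rename_map.apply(names)


def load_rename_map(path: str | Path) -> RenameMap:
    """Read a rename map TSV with columns old_name, new_name, swap (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"old_name", "new_name", "swap"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rename map {path} missing columns: {sorted(missing)}")
    entries = tuple(
        RenameEntry(row["old_name"], row["new_name"], bool(int(row["swap"])))
        for _, row in df.iterrows()
    )
    return RenameMap(entries)


def default_rename_map() -> RenameMap:
    """The packaged harmonization map (20 renames + 1 swapped pair)."""
    ref = importlib.resources.files("chcscreen.data") / "rename_map.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_rename_map(path)
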