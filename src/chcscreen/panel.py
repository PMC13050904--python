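"""Hydrocarbon stimulus panel: identity, structure and cuticle-presence flags.

The screening panel used throughout the package is a set of long-chain
hydrocarbons (n-alkanes, methyl-branched alkanes and alkenes) delivered at a
fixed dose from heated cartridges, plus a pentane solvent control.  A subset
of the panel occurs naturally on the ant cuticle; that flag is carried per
hydrocarbon so downstream figures and summaries can distinguish ecologically
occurring ligands from receptive-range probes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

HC_CLASSES = ("n-alkane", "monomethyl", "dimethyl", "alkene")

#: Screening dose applied to each cartridge, in nmol.
DEFAULT_DOSE_NMOL = 20.0

#: Name of the solvent control stimulus.
SOLVENT = "pentane"


@dataclass(frozen=True)
class Hydrocarbon:
    """One panel member: a hydrocarbon with backbone length and class.

    ``chain_length`` counts backbone carbons (for ``13-MeC31`` it is 31, the
    methyl branch is not counted).  ``on_cuticle`` marks hydrocarbons found
    in cuticular extracts of the study species.
    """

    name: str
    chain_length: int
    hc_class: str
    methyl_positions: tuple[int, ...] = ()
    double_bond: str | None = None  # e.g. "Z9"
    on_cuticle: bool = False

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError(f"{self.name}: chain_length must be >= 1")
        if self.hc_class not in HC_CLASSES:
            raise ValueError(
                f"{self.name}: unknown hc_class {self.hc_class!r}; "
                f"expected one of {HC_CLASSES}"
            )
        n_methyl = len(self.methyl_positions)
        expected = {"n-alkane": 0, "monomethyl": 1, "dimethyl": 2, "alkene": 0}
        if n_methyl != expected[self.hc_class]:
            raise ValueError(
                f"{self.name}: hc_class {self.hc_class!r} requires "
                f"{expected[self.hc_class]} methyl position(s), got {n_methyl}"
            )
        if self.hc_class == "alkene":
            if not self.double_bond:
                raise ValueError(f"{self.name}: alkene requires a double bond")
        elif self.double_bond:
            raise ValueError(f"{self.name}: only alkenes carry a double bond")


@dataclass(frozen=True)
class StimulusPanel:
    """Ordered hydrocarbon panel plus its solvent control."""

    hydrocarbons: tuple[Hydrocarbon, ...]
    solvent_name: str = SOLVENT
    default_dose_nmol: float = DEFAULT_DOSE_NMOL

    def __post_init__(self) -> None:
        names = [hc.name for hc in self.hydrocarbons]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate hydrocarbon names in panel: {sorted(dupes)}")
        if self.solvent_name in names:
            raise ValueError(f"solvent {self.solvent_name!r} must not be a panel member")

    def __len__(self) -> int:
        return len(self.hydrocarbons)

    def __iter__(self) -> Iterator[Hydrocarbon]:
        return iter(self.hydrocarbons)

    def __getitem__(self, name: str) -> Hydrocarbon:
        for hc in self.hydrocarbons:
            if hc.name == name:
                return hc
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [hc.name for hc in self.hydrocarbons]

    @property
    def chain_lengths(self) -> dict[str, int]:
        return {hc.name: hc.chain_length for hc in self.hydrocarbons}

    @property
    def cuticular(self) -> list[str]:
        """Names of panel members found on the cuticle."""
        return [hc.name for hc in self.hydrocarbons if hc.on_cuticle]


def _parse_row(row: pd.Series) -> Hydrocarbon:
    methyl = ()
    raw = row.get("methyl_positions")
    if isinstance(raw, str) and raw.strip():
        methyl = tuple(int(p) for p in raw.split(","))
    bond = row.get("double_bond")
    bond = bond.strip() if isinstance(bond, str) and bond.strip() else None
    return Hydrocarbon(
        name=str(row["name"]),
        chain_length=int(row["chain_length"]),
        hc_class=str(row["hc_class"]),
        methyl_positions=methyl,
        double_bond=bond,
        on_cuticle=bool(int(row["on_cuticle"])),
    )


def load_panel(path: str | Path) -> StimulusPanel:
    """Read a stimulus panel from a TSV file.

    Expected columns: ``name``, ``chain_length``, ``hc_class``,
    ``methyl_positions`` (comma-joined, may be empty), ``double_bond``
    (may be empty), ``on_cuticle`` (0/1).  Lines starting with ``#`` are
    comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"panel file {path} contains no hydrocarbons")
    required = {"name", "chain_length", "hc_class", "on_cuticle"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} missing columns: {sorted(missing)}")
    hcs = tuple(_parse_row(row) for _, row in df.iterrows())
    return StimulusPanel(hydrocarbons=hcs)


def default_panel() -> StimulusPanel:
    """The packaged 39-hydrocarbon screening panel (17 flagged on-cuticle)."""
    ref = importlib.resources.files("chcscreen.data") / "panel.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_panel(path)
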