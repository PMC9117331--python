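"""Visual-barcode panels and barcode-space combinatorics.

A visual barcode is a fluorescent protein (the *fluorophore*) targeted to a
specific subcellular compartment (the *localization*).  A panel fixes the set
of fluorophores and localization patterns available to an experiment and the
(fluorophore, localization) pairs actually in use as clone labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

#: Localization patterns the image generator knows how to render.
LOCALIZATIONS = ("whole_cell", "cytoplasmic", "nuclear", "peroxisome", "er")

#: Default fluorophore channel names (blue/cyan/green/yellow FPs).
DEFAULT_FLUOROPHORES = ("BFP", "CFP", "GFP", "YFP")

#: The three localizations retained for the 12-plex panel (nuclear and ER are
#: the most mutually confusable patterns and are left out of the default mix).
DEFAULT_PANEL_LOCALIZATIONS = ("whole_cell", "cytoplasmic", "peroxisome")


@dataclass(frozen=True)
class BarcodePanel:
    """A set of (fluorophore, localization) visual barcodes.

    Parameters
    ----------
    fluorophores
        Channel names, one imaging channel per fluorophore.
    localizations
        Localization pattern names, each drawn from :data:`LOCALIZATIONS`.
    barcodes
        The (fluorophore, localization) pairs in use.  Defaults to the full
        cartesian product.
    """

    fluorophores: tuple[str, ...]
    localizations: tuple[str, ...]
    barcodes: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.barcodes:
            object.__setattr__(
                self,
                "barcodes",
                tuple(itertools.product(self.fluorophores, self.localizations)),
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique (fluorophore, localization) pairs")
        for fluor, loc in self.barcodes:
            if fluor not in self.fluorophores:
                raise ValueError(f"unknown fluorophore {fluor!r}")
            if loc not in self.localizations:
                raise ValueError(f"unknown localization {loc!r}")
        for loc in self.localizations:
            if loc not in LOCALIZATIONS:
                raise ValueError(
                    f"unsupported localization {loc!r}; choose from {LOCALIZATIONS}"
                )

    @property
    def clone_names(self) -> tuple[str, ...]:
        return tuple(f"{f}-{loc}" for f, loc in self.barcodes)

    def __len__(self) -> int:
        return len(self.barcodes)


def default_panel() -> BarcodePanel:
    """The 12-clone panel: 4 fluorophores x 3 localizations."""
    return BarcodePanel(DEFAULT_FLUOROPHORES, DEFAULT_PANEL_LOCALIZATIONS)


def enumerate_single_barcodes(
    fluorophores: int | tuple[str, ...] = 4,
    localizations: int | tuple[str, ...] = 5,
) -> list[tuple[str, str]]:
    """All single-protein barcodes: the cartesian product of colors and patterns.

    With 4 fluorescent proteins and 5 localizations this yields 20 barcodes.
    """
    fluors = _names(fluorophores, "F")
    locs = _names(localizations, "L")
    return list(itertools.product(fluors, locs))


def enumerate_dual_barcodes(
    fluorophores: int | tuple[str, ...] = 4,
    localizations: int | tuple[str, ...] = 5,
) -> list[frozenset[tuple[str, str]]]:
    """All dual-protein barcodes: unordered pairs of single barcodes in one cell.

    The two proteins must occupy *different localizations* so that each
    contributes an independent pattern (they may share a fluorophore, in
    which case that channel shows the union of the two patterns, still a
    unique readout).  With 4 fluorophores and 5 localizations each single
    barcode pairs with the 16 barcodes of a different localization:
    20 * 16 / 2 = 160 dual barcodes.
    """
    singles = enumerate_single_barcodes(fluorophores, localizations)
    pairs = []
    for (f1, l1), (f2, l2) in itertools.combinations(singles, 2):
        if l1 != l2:
            pairs.append(frozenset([(f1, l1), (f2, l2)]))
    return pairs


def _names(source: int | tuple[str, ...], prefix: str) -> tuple[str, ...]:
    if isinstance(source, int):
        return tuple(f"{prefix}{i}" for i in range(source))
    return tuple(source)
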