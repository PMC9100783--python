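"""Desikan-Killiany ROI id conventions.

The feature tensors index 68 cortical regions of interest (ROIs): the 34
Desikan-Killiany parcels, one per hemisphere.  The id scheme reconstructed
from the published centrality tables is

    roi_id = 2*a - 1  (left hemisphere)
    roi_id = 2*a      (right hemisphere)

where ``a`` is the 1-based alphabetical rank of the parcel name (so 1 is
``bankssts L``, 2 is ``bankssts R``, ..., 68 is ``transversetemporal R``).
The source study does not print its full id table; this mapping is a
reconstruction validated against every (id, name, hemisphere) triple it does
print, and can be overridden with a user-supplied atlas file.
"""

from __future__ import annotations

import csv
from pathlib import Path

__all__ = ["DK_REGIONS", "N_ROI", "AtlasMap", "roi_name", "default_atlas"]

#: The 34 Desikan-Killiany cortical parcel names in alphabetical order.
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

N_ROI = 2 * len(DK_REGIONS)


class AtlasMap:
    """Mapping roi_id (1..68) -> (region name, hemisphere).

    Parameters
    ----------
    entries
        Optional explicit mapping ``{roi_id: (region, hemisphere)}`` with
        hemisphere in ``{"L", "R"}``.  When omitted the reconstructed
        alphabetical Desikan-Killiany scheme is used.
    """

    def __init__(self, entries: dict[int, tuple[str, str]] | None = None):
        if entries is None:
            entries = {}
            for a, region in enumerate(DK_REGIONS, start=1):
                entries[2 * a - 1] = (region, "L")
                entries[2 * a] = (region, "R")
        ids = sorted(entries)
        if ids != list(range(1, len(entries) + 1)):
            raise ValueError("atlas ids must be contiguous starting at 1")
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, roi_id: int) -> tuple[str, str]:
        try:
            return self._entries[int(roi_id)]
        except KeyError:
            raise KeyError(
                f"roi_id {roi_id} outside 1..{len(self._entries)}"
            ) from None

    def label(self, roi_id: int) -> str:
        region, hemi = self[roi_id]
        return f"{region} {hemi}"

    def items(self):
        return self._entries.items()

    @classmethod
    def from_file(cls, path: str | Path) -> "AtlasMap":
        """Load a custom atlas from a delimited file with columns
        ``roi_id, region, hemisphere``."""
        entries: dict[int, tuple[str, str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            sample = fh.read(4096)
            fh.seek(0)
            dialect = csv.Sniffer().sniff(sample, delimiters=",\t")
            for row in csv.DictReader(fh, dialect=dialect):
                hemi = row["hemisphere"].strip().upper()
                if hemi not in ("L", "R"):
                    raise ValueError(f"hemisphere must be L or R, got {hemi!r}")
                entries[int(row["roi_id"])] = (row["region"].strip(), hemi)
        return cls(entries)


_DEFAULT = None


def default_atlas() -> AtlasMap:
    """The packaged (reconstructed) 68-ROI Desikan-Killiany atlas."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = AtlasMap()
    return _DEFAULT


def roi_name(roi_id: int) -> tuple[str, str]:
    """Return ``(region, hemisphere)`` for a 1-based ROI id.

    >>> roi_name(8)
    ('cuneus', 'R')
    >>> roi_name(63)
    ('supramarginal', 'L')
    """
    roi_id = int(roi_id)
    if not 1 <= roi_id <= N_ROI:
        raise ValueError(f"roi_id must be in 1..{N_ROI}, got {roi_id}")
    return default_atlas()[roi_id]
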