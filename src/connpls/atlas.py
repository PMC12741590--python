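"""Parcellation tables: region -> gyrus -> lobe memberships.

The default table follows the Brainnetome layout: 246 grey-matter regions
(210 cortical, 36 subcortical) grouped into 24 gyri and 7 lobes. Reduced
synthetic parcellations with the same gyrus/lobe vocabulary are available for
small simulated connectomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Parcellation",
    "default_parcellation",
    "synthetic_parcellation",
    "load_parcellation",
]

# gyrus, lobe, number of regions, tissue class. Cortical counts sum to 210,
# subcortical to 36; 24 gyri, 7 lobes.
_GYRI: list[tuple[str, str, int, str]] = [
    ("SFG", "Frontal", 14, "cortical"),
    ("MFG", "Frontal", 14, "cortical"),
    ("IFG", "Frontal", 12, "cortical"),
    ("OrG", "Frontal", 12, "cortical"),
    ("PrG", "Frontal", 12, "cortical"),
    ("PCL", "Frontal", 4, "cortical"),
    ("STG", "Temporal", 12, "cortical"),
    ("MTG", "Temporal", 8, "cortical"),
    ("ITG", "Temporal", 14, "cortical"),
    ("FuG", "Temporal", 6, "cortical"),
    ("PhG", "Temporal", 12, "cortical"),
    ("pSTS", "Temporal", 4, "cortical"),
    ("SPL", "Parietal", 10, "cortical"),
    ("IPL", "Parietal", 12, "cortical"),
    ("Pcun", "Parietal", 8, "cortical"),
    ("PoG", "Parietal", 8, "cortical"),
    ("INS", "Insular", 12, "cortical"),
    ("CG", "Limbic", 14, "cortical"),
    ("MVOcC", "Occipital", 10, "cortical"),
    ("LOcC", "Occipital", 12, "cortical"),
    ("Amyg", "Subcortical", 4, "subcortical"),
    ("Hipp", "Subcortical", 4, "subcortical"),
    ("BG", "Subcortical", 12, "subcortical"),
    ("Tha", "Subcortical", 16, "subcortical"),
]

GYRUS_NAMES = [g for g, _, _, _ in _GYRI]
LOBE_NAMES = ["Frontal", "Temporal", "Parietal", "Insular", "Limbic", "Occipital", "Subcortical"]


@dataclass(frozen=True)
class Parcellation:
    """Region-to-partition lookup backed by a 4+ column table.

    Columns: ``region_id`` (1..n, contiguous), ``region_name``, ``gyrus``,
    ``lobe``, ``tissue_class``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"region_id", "region_name", "gyrus", "lobe"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        ids = self.table["region_id"].to_numpy()
        n = len(ids)
        if n == 0:
            raise ValueError("empty parcellation")
        if sorted(ids.tolist()) != list(range(1, n + 1)):
            raise ValueError("region_id must be contiguous 1..n with no gaps or duplicates")
        if self.table[["gyrus", "lobe"]].isna().any().any():
            bad = self.table.loc[self.table[["gyrus", "lobe"]].isna().any(axis=1), "region_id"]
            raise ValueError(f"regions missing a partition label: {bad.tolist()}")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def labels(self, level: str) -> pd.Series:
        """Partition label per region (ordered by region_id), level in {gyrus, lobe}."""
        if level not in ("gyrus", "lobe"):
            raise ValueError(f"level must be 'gyrus' or 'lobe', got {level!r}")
        t = self.table.sort_values("region_id")
        return t.set_index("region_id")[level]

    def partition_names(self, level: str) -> list[str]:
        """Partition labels in first-appearance (atlas) order."""
        lab = self.labels(level)
        seen: list[str] = []
        for v in lab:
            if v not in seen:
                seen.append(v)
        return seen

    def validate_brainnetome(self) -> None:
        """Check the 246 = 210 cortical + 36 subcortical / 24 gyri / 7 lobes layout."""
        if self.n_regions != 246:
            raise ValueError(f"expected 246 regions, got {self.n_regions}")
        tc = self.table["tissue_class"].value_counts()
        if tc.get("cortical", 0) != 210 or tc.get("subcortical", 0) != 36:
            raise ValueError(f"expected 210 cortical + 36 subcortical, got {tc.to_dict()}")
        if self.table["gyrus"].nunique() != 24:
            raise ValueError("expected 24 gyri")
        if self.table["lobe"].nunique() != 7:
            raise ValueError("expected 7 lobes")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_parcellation() -> Parcellation:
    """The 246-region table (210 cortical + 36 subcortical, 24 gyri, 7 lobes)."""
    rows = []
    rid = 0
    for gyrus, lobe, count, tissue in _GYRI:
        for k in range(count):
            rid += 1
            rows.append((rid, f"{gyrus}_{k + 1}", gyrus, lobe, tissue))
    table = pd.DataFrame(rows, columns=["region_id", "region_name", "gyrus", "lobe", "tissue_class"])
    parc = Parcellation(table)
    parc.validate_brainnetome()
    return parc


def synthetic_parcellation(n_regions: int) -> Parcellation:
    """Reduced parcellation for small simulated connectomes.

    Regions are dealt to the 24 gyri proportionally to the full-atlas gyrus
    sizes (largest-remainder rounding), preserving the gyrus->lobe map, so
    gyrus/lobe aggregation is exercised at any problem size.
    """
    if n_regions == 246:
        return default_parcellation()
    if n_regions < 1:
        raise ValueError("n_regions must be positive")
    total = sum(c for _, _, c, _ in _GYRI)
    quotas = [c * n_regions / total for _, _, c, _ in _GYRI]
    counts = [int(q) for q in quotas]
    remainders = sorted(range(len(_GYRI)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in remainders[: n_regions - sum(counts)]:
        counts[i] += 1
    rows = []
    rid = 0
    for (gyrus, lobe, _, tissue), cnt in zip(_GYRI, counts):
        for k in range(cnt):
            rid += 1
            rows.append((rid, f"{gyrus}_{k + 1}", gyrus, lobe, tissue))
    return Parcellation(pd.DataFrame(rows, columns=["region_id", "region_name", "gyrus", "lobe", "tissue_class"]))


def load_parcellation(path) -> Parcellation:
    """Read a delimited parcellation table (tab/comma sniffed from the header)."""
    table = pd.read_csv(path, sep=None, engine="python")
    if "tissue_class" not in table.columns:
        table = table.assign(
            tissue_class=[
                "subcortical" if lobe == "Subcortical" else "cortical" for lobe in table["lobe"]
            ]
        )
    return Parcellation(table)
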