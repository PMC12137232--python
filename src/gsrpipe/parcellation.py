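"""Cortical parcellation scheme: 114 ROIs, 17 functional networks, 8 network groups.

The default scheme is a deterministic synthetic stand-in for a 114-ROI
cortical atlas organised into 17 functional networks (two visual, two
somatomotor, two dorsal-attention, two salience/ventral-attention, two
limbic, three control, three default-mode networks plus a temporoparietal
network).  Users may supply their own scheme as a TSV with columns
``roi_id``, ``network17``, ``group``, ``hemisphere``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NETWORK17_NAMES = (
    "VisCent", "VisPeri",
    "SomMotA", "SomMotB",
    "DorsAttnA", "DorsAttnB",
    "SalVentAttnA", "SalVentAttnB",
    "LimbicA", "LimbicB",
    "ContA", "ContB", "ContC",
    "DefaultA", "DefaultB", "DefaultC",
    "TempPar",
)

#: network -> coarse group (8 groups; 7 of them are the usual reporting panels,
#: TempPar participates in whole-brain summaries only)
NETWORK_TO_GROUP = {
    "VisCent": "Visual", "VisPeri": "Visual",
    "SomMotA": "SomMot", "SomMotB": "SomMot",
    "DorsAttnA": "DorsAttn", "DorsAttnB": "DorsAttn",
    "SalVentAttnA": "SalVentAttn", "SalVentAttnB": "SalVentAttn",
    "LimbicA": "Limbic", "LimbicB": "Limbic",
    "ContA": "Cont", "ContB": "Cont", "ContC": "Cont",
    "DefaultA": "Default", "DefaultB": "Default", "DefaultC": "Default",
    "TempPar": "TempPar",
}

GROUP_NAMES = ("Visual", "SomMot", "DorsAttn", "SalVentAttn",
               "Limbic", "Cont", "Default", "TempPar")


@dataclass(frozen=True)
class ParcellationScheme:
    """Mapping of ROIs to networks, groups and hemispheres."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"roi_id", "network17", "group", "hemisphere"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        if t["roi_id"].duplicated().any():
            dup = t.loc[t["roi_id"].duplicated(), "roi_id"].tolist()
            raise ValueError(f"duplicate roi_id values: {dup}")
        ids = sorted(t["roi_id"])
        if ids != list(range(1, len(t) + 1)):
            raise ValueError("roi_id must be the consecutive integers 1..n_rois")
        unknown = set(t["network17"]) - set(NETWORK17_NAMES)
        if unknown:
            raise ValueError(f"unknown network labels: {sorted(unknown)}")
        # a network must never straddle two groups
        for net, sub in t.groupby("network17"):
            groups = set(sub["group"])
            if len(groups) != 1:
                raise ValueError(f"network {net} maps to multiple groups: {sorted(groups)}")
            if NETWORK_TO_GROUP[net] not in groups:
                raise ValueError(f"network {net} assigned to unexpected group {groups}")
        counts = t["network17"].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"networks with fewer than 2 ROIs: {sorted(small.index)}")
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere labels must be L/R, got {sorted(bad_hemi)}")

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        return [n for n in NETWORK17_NAMES if n in set(self.table["network17"])]

    @property
    def roi_labels(self) -> list[str]:
        return [f"ROI{int(i):03d}" for i in self.table["roi_id"]]

    def network_of_roi(self) -> pd.Series:
        """Series indexed by ROI label giving the 17-network membership."""
        return pd.Series(self.table["network17"].values, index=self.roi_labels)

    def group_of_network(self) -> dict[str, str]:
        return {n: NETWORK_TO_GROUP[n] for n in self.networks}

    def members(self, network: str) -> list[str]:
        mask = self.table["network17"] == network
        return [f"ROI{int(i):03d}" for i in self.table.loc[mask, "roi_id"]]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def make_parcellation(n_rois: int = 114, scheme_table: str | Path | None = None
                      ) -> ParcellationScheme:
    """Build the default 114-ROI/17-network scheme or load a user table.

    The default scheme distributes 114 ROIs over the 17 networks (12
    networks of 7 ROIs and 5 of 6) and alternates hemispheres within each
    network.  It is fully deterministic.
    """
    if scheme_table is not None:
        table = pd.read_csv(scheme_table, sep="\t")
        return ParcellationScheme(table)
    if n_rois != 114:
        raise ValueError("the default scheme is defined for n_rois=114; "
                         "supply scheme_table for other parcellations")
    sizes = [7] * 12 + [6] * 5  # 12*7 + 5*6 = 114
    rows = []
    roi = 1
    for net, size in zip(NETWORK17_NAMES, sizes):
        for j in range(size):
            rows.append({
                "roi_id": roi,
                "network17": net,
                "group": NETWORK_TO_GROUP[net],
                "hemisphere": "L" if j % 2 == 0 else "R",
            })
            roi += 1
    return ParcellationScheme(pd.DataFrame(rows))
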