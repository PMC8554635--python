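"""Community data container: long-format abundance records plus site flow intermittence."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

RECORD_COLUMNS = ["river", "site", "date", "taxon", "abundance"]
FI_COLUMNS = ["river", "site", "fi"]


class CommunityDataError(ValueError):
    """Raised when community records or the FI table are malformed."""


@dataclass
class CommunityData:
    """Invertebrate samples across rivers, sites and dates.

    Attributes
    ----------
    records
        Long table with columns (river, site, date, taxon, abundance);
        one row per taxon occurrence in one sample.
    fi
        Per-site table (river, site, fi) with flow intermittence as the
        percentage of the year without surface flow, in [0, 100].
    truth
        Generating parameters when the data are synthetic (empty for
        field data); kept so recovery tests can compare against them.
    """

    records: pd.DataFrame
    fi: pd.DataFrame
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise CommunityDataError(f"records missing columns: {missing}")
        missing = [c for c in FI_COLUMNS if c not in self.fi.columns]
        if missing:
            raise CommunityDataError(f"FI table missing columns: {missing}")
        if (self.records["abundance"] < 0).any():
            raise CommunityDataError("negative abundances")
        bad_fi = self.fi[(self.fi["fi"] < 0) | (self.fi["fi"] > 100)]
        if len(bad_fi):
            raise CommunityDataError(
                f"FI outside [0, 100] for sites: {sorted(bad_fi['site'].tolist())}"
            )
        rec_sites = set(self.records["site"])
        fi_sites = set(self.fi["site"])
        if not rec_sites <= fi_sites:
            raise CommunityDataError(
                f"sites without FI value: {sorted(rec_sites - fi_sites)}"
            )

    @property
    def taxa(self) -> list[str]:
        return sorted(self.records["taxon"].unique())

    @property
    def sites(self) -> list[str]:
        return sorted(self.fi["site"].unique())

    def site_fi(self) -> pd.Series:
        """Site -> FI (%)."""
        return self.fi.set_index("site")["fi"]

    def river_of_site(self) -> pd.Series:
        """Site -> river label."""
        return self.fi.set_index("site")["river"]
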