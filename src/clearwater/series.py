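"""SiteSeries: one site's ordered weekly observations.

The universal input of the pipeline. Wraps a pandas DataFrame with a
``date`` column plus the measured columns of :mod:`clearwater.columns`;
derived community columns (totals, relative abundances) are recomputed on
construction. Missing weeks are represented as date gaps, not as NaN rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import columns as C


class SeriesError(ValueError):
    """Raised when a weekly series violates its contract."""


@dataclass
class SiteSeries:
    """Weekly multivariate observations for a single site.

    Parameters
    ----------
    site : str
        Site identifier.
    data : pandas.DataFrame
        One row per sampled week with a ``date`` column (datetime64) and any
        subset of the measured columns. Rows must be strictly increasing in
        date. Derived columns (``total_phyto``, ``total_zoo``, taxon relative
        abundances in percent) are recomputed here when their constituents
        are present.
    """

    site: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        if C.DATE not in df.columns:
            raise SeriesError(f"site {self.site!r}: missing 'date' column")
        df[C.DATE] = pd.to_datetime(df[C.DATE]).astype("datetime64[ns]")
        if not df[C.DATE].is_monotonic_increasing or df[C.DATE].duplicated().any():
            raise SeriesError(f"site {self.site!r}: dates must be strictly increasing")
        df = df.reset_index(drop=True)

        phyto = ["cyanobacteria", "diatoms", "green_algae", "other_algae"]
        zoo = ["rotifera", "cladocera", "copepoda"]
        if all(c in df.columns for c in phyto):
            df["total_phyto"] = df[phyto].sum(axis=1)
        if all(c in df.columns for c in zoo):
            tz = df[zoo].sum(axis=1)
            df["total_zoo"] = tz
            with np.errstate(divide="ignore", invalid="ignore"):
                for taxon in zoo:
                    ra = np.where(tz > 0, 100.0 * df[taxon] / tz, np.nan)
                    df[f"{taxon}_ra"] = ra

        for col in C.NON_NEGATIVE:
            if col in df.columns:
                vals = df[col].to_numpy(dtype=float)
                if np.nanmin(vals, initial=0.0) < 0:
                    bad = int(np.nanargmin(vals))
                    raise SeriesError(
                        f"site {self.site!r}: negative {col} at row {bad}"
                    )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.Series:
        return self.data[C.DATE]

    def gap_breaks(self, max_gap_days: int = 9) -> np.ndarray:
        """Boolean array over the n-1 transitions; True where the step
        between consecutive sampled weeks exceeds ``max_gap_days`` (a missing
        week). Event runs must never span such a break."""
        d = self.dates.to_numpy()
        steps = (d[1:] - d[:-1]) / np.timedelta64(1, "D")
        return steps > max_gap_days

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)
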