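"""Robust-design count data: in-memory container and CSV round-trip.

A dataset is a set of transects surveyed on repeat nights (closed secondary
surveys) within 6-month seasons (open primary periods).  Counts are stored
per species as a float array of shape (transects, surveys, seasons) with NaN
marking transect-seasons that were not surveyed.

The canonical on-disk form is a long CSV with one row per
transect x season x survey:

    transect_id, season_index, season_type, survey_index, length_km,
    count_rabbit, count_cat

Missing surveys keep their row with empty count fields, so the survey design
(including missingness) survives the round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .process import BREEDING, NONBREEDING

__all__ = ["CountData", "read_counts_csv", "write_counts_csv"]


@dataclass
class CountData:
    """Observed robust-design counts for one or more species.

    Attributes
    ----------
    y : dict of str -> ndarray
        Per-species counts, shape (n_transects, n_surveys, n_seasons),
        float with NaN for missing cells.
    lengths_km : ndarray
        Transect lengths, shape (n_transects, n_seasons); a 1-D vector is
        broadcast across seasons.
    season_type : list of str
        Per-season labels, alternating "breeding"/"nonbreeding".
    transect_ids : list
        Transect identifiers (row order of ``y``).
    """

    y: dict[str, np.ndarray]
    lengths_km: np.ndarray
    season_type: list[str]
    transect_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {s: a.shape for s, a in self.y.items()}
        if len({v for v in shapes.values()}) > 1:
            raise ValueError(f"species count arrays disagree in shape: {shapes}")
        shape = next(iter(shapes.values()))
        if len(shape) != 3:
            raise ValueError("count arrays must be (transects, surveys, seasons)")
        self.y = {s: np.asarray(a, dtype=float) for s, a in self.y.items()}
        L = np.asarray(self.lengths_km, dtype=float)
        if L.ndim == 1:
            L = np.repeat(L[:, None], shape[2], axis=1)
        if L.shape != (shape[0], shape[2]):
            raise ValueError("lengths_km must be (n_transects,) or (n_transects, n_seasons)")
        if np.any(L[np.isfinite(L)] <= 0):
            raise ValueError("transect lengths must be positive")
        self.lengths_km = L
        if len(self.season_type) != shape[2]:
            raise ValueError("season_type length must equal the number of seasons")
        bad = set(self.season_type) - {BREEDING, NONBREEDING}
        if bad:
            raise ValueError(f"unknown season labels: {sorted(bad)}")
        if not self.transect_ids:
            self.transect_ids = list(range(shape[0]))

    @property
    def species(self) -> list[str]:
        return list(self.y)

    @property
    def n_transects(self) -> int:
        return next(iter(self.y.values())).shape[0]

    @property
    def n_surveys(self) -> int:
        return next(iter(self.y.values())).shape[1]

    @property
    def n_seasons(self) -> int:
        return next(iter(self.y.values())).shape[2]

    @property
    def obs_mask(self) -> np.ndarray:
        """(transects, seasons) boolean: True where the cell was surveyed."""
        any_obs = np.zeros((self.n_transects, self.n_seasons), dtype=bool)
        for arr in self.y.values():
            any_obs |= np.any(np.isfinite(arr), axis=1)
        return any_obs

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, tid in enumerate(self.transect_ids):
            for k in range(self.n_seasons):
                for j in range(self.n_surveys):
                    row = {
                        "transect_id": tid,
                        "season_index": k,
                        "season_type": self.season_type[k],
                        "survey_index": j,
                        "length_km": self.lengths_km[i, k],
                    }
                    for s in self.species:
                        row[f"count_{s}"] = self.y[s][i, j, k]
                    rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountData":
        species = [c[len("count_"):] for c in df.columns if c.startswith("count_")]
        if not species:
            raise ValueError("no count_<species> columns found")
        tids = list(pd.unique(df["transect_id"]))
        seasons = np.sort(pd.unique(df["season_index"].astype(int)))
        surveys = np.sort(pd.unique(df["survey_index"].astype(int)))
        I, J, K = len(tids), len(surveys), len(seasons)
        ti = {t: i for i, t in enumerate(tids)}
        ki = {int(k): idx for idx, k in enumerate(seasons)}
        ji = {int(j): idx for idx, j in enumerate(surveys)}
        y = {s: np.full((I, J, K), np.nan) for s in species}
        lengths = np.full((I, K), np.nan)
        season_type = [None] * K
        for _, r in df.iterrows():
            i, j, k = ti[r["transect_id"]], ji[int(r["survey_index"])], ki[int(r["season_index"])]
            season_type[k] = str(r["season_type"])
            lengths[i, k] = float(r["length_km"])
            for s in species:
                v = r[f"count_{s}"]
                if pd.notna(v):
                    y[s][i, j, k] = float(v)
        # per-transect fill of lengths for seasons never visited
        for i in range(I):
            row = lengths[i]
            if np.all(np.isnan(row)):
                raise ValueError(f"transect {tids[i]} has no recorded length")
            row[np.isnan(row)] = np.nanmean(row)
        if any(st is None for st in season_type):
            raise ValueError("some seasons have no season_type label")
        return cls(y=y, lengths_km=lengths, season_type=season_type, transect_ids=tids)


def write_counts_csv(data: CountData, path) -> None:
    df = data.to_dataframe()
    df.to_csv(path, index=False, float_format="%.6g")


def read_counts_csv(path) -> CountData:
    return CountData.from_dataframe(pd.read_csv(path))
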