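"""Abridged life tables and between-scenario life-expectancy differences.

From a survivor series :math:`l_x` on 5-year age bands the table derives
person-years lived in each band (:math:`L_x`, deaths spread within the band
by a fraction ``ax_fraction``, default mid-band), cumulative person-years
remaining (:math:`T_x`) by backward summation, and remaining life
expectancy :math:`e_x = T_x / l_x`. The final band is open-ended; its
person-years are :math:`l / h` with :math:`h` the closing per-year hazard
(supplied, or derived from the last modelled interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "build_life_table", "additional_expected_years"]


@dataclass
class LifeTable:
    """Abridged life-table columns on 5-year bands."""

    ages: list[int]
    l: np.ndarray  # survivors at band start
    T: np.ndarray  # person-years remaining at band start
    L: np.ndarray | None = None  # person-years lived within band

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if np.any(np.diff(self.l) > 1e-9 * max(self.l[0], 1.0)):
            raise ValueError("survivor column must be non-increasing")

    @property
    def e(self) -> np.ndarray:
        """Expectation of remaining life, years."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.l > 0, self.T / self.l, 0.0)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"age": self.ages, "l_x": self.l, "T_x": self.T, "e_x": self.e})
        if self.L is not None:
            out["L_x"] = self.L
        return out

    @classmethod
    def from_columns(cls, ages, l, T) -> "LifeTable":
        """Build from published l/T columns (no within-band detail)."""
        return cls(list(ages), np.asarray(l, float), np.asarray(T, float))


def build_life_table(
    survivors,
    *,
    final_band_open: bool = True,
    ax_fraction: float = 0.5,
    final_e: float | None = None,
    final_hazard_per_year: float | None = None,
    band_width: float = 5.0,
) -> LifeTable:
    """Build an abridged life table from survivors at 5-year band starts.

    ``survivors`` is a mapping/Series age→l_x (non-increasing, positive at
    the start). For closed bands
    ``L_x = w·(l_{x+w} + ax_fraction·(l_x − l_{x+w}))`` (``ax_fraction=0.5``
    is the trapezoid / uniform-deaths rule). For the open final band, person
    years are ``l·final_e`` when an expectancy is supplied, else
    ``l / final_hazard_per_year``; with neither, the hazard of the last
    closed interval is carried forward.
    """
    if isinstance(survivors, pd.Series):
        ages = [int(a) for a in survivors.index]
        l = survivors.to_numpy(dtype=float)
    else:
        ages = sorted(int(a) for a in survivors)
        l = np.array([float(survivors[a]) for a in ages])
    if l[0] <= 0:
        raise ValueError("survivors must be positive at the first band")
    if np.any(np.diff(l) > 1e-9 * l[0]):
        raise ValueError("survivor series must be non-increasing")
    if not 0.0 <= ax_fraction <= 1.0:
        raise ValueError("ax_fraction must be in [0, 1]")

    L = np.empty_like(l)
    L[:-1] = band_width * (l[1:] + ax_fraction * (l[:-1] - l[1:]))

    l_last = l[-1]
    if not final_band_open or l_last == 0:
        L[-1] = band_width * ax_fraction * l_last
    elif final_e is not None:
        L[-1] = l_last * final_e
    else:
        if final_hazard_per_year is None:
            if len(l) < 2 or l[-2] <= 0 or l_last <= 0:
                raise ValueError("cannot derive a closing hazard from this series")
            final_hazard_per_year = -np.log(l_last / l[-2]) / band_width
        if final_hazard_per_year <= 0:
            raise ValueError("closing hazard must be > 0 for an open final band")
        L[-1] = l_last / final_hazard_per_year

    T = np.cumsum(L[::-1])[::-1]
    return LifeTable(ages, l, T, L)


def additional_expected_years(lt_modified: LifeTable, lt_base: LifeTable) -> pd.DataFrame:
    """Per-band survivor and person-years-remaining differences.

    Returns the Modified-minus-Base ``l_x`` and ``T_x`` differences: extra
    survivors alive at each band start and the additional years of expected
    life they represent.
    """
    if list(lt_modified.ages) != list(lt_base.ages):
        raise ValueError("life tables have mismatched age bands")
    return pd.DataFrame(
        {
            "age": lt_modified.ages,
            "l_modified": lt_modified.l,
            "T_modified": lt_modified.T,
            "l_base": lt_base.l,
            "T_base": lt_base.T,
            "l_diff": lt_modified.l - lt_base.l,
            "T_diff": lt_modified.T - lt_base.T,
        }
    )
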