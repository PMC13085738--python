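"""Cleaner selectivity (electivity) index.

Quantifies how a cleaner allocates cleaning time among client species
relative to each species' availability at the station, following the
Vanderploeg–Scavia electivity family: a normalized use/availability ratio

    W_i = (r_i / p_i) / sum_j (r_j / p_j)

mapped onto a symmetric preference scale

    E_i = (W_i - 1/n) / (W_i + 1/n)

where ``r_i`` is the proportion of total cleaning time spent on species
``i``, ``p_i`` the availability proportion of species ``i`` from frame
censuses, and ``n`` the richness of cleaned client species.  E ranges
from -1 (strong avoidance) through 0 (use proportional to availability)
to +1 (strong preference).

A station-replicate survey is summarised by the unweighted mean of E
over the cleaned species (``station_selectivity``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "electivity_W",
    "electivity_E",
    "station_selectivity",
    "SelectivityResult",
]


@dataclass
class SelectivityResult:
    """Per-species electivity at one station-replicate survey.

    Attributes
    ----------
    species : list of str
        Cleaned species (or families, in family mode), index for W and E.
    W : ndarray
        Normalized use/availability weights; sums to 1.
    E : ndarray
        Electivity per species, each in [-1, 1].
    station_value : float
        Unweighted mean of E over cleaned species; NaN when undefined.
    flags : list of str
        Degeneracy notes (no cleans, zero-length cleans, availability
        floor applied, single-species station).
    """

    species: list
    W: np.ndarray
    E: np.ndarray
    station_value: float
    flags: list = field(default_factory=list)


def electivity_W(r, p):
    """Normalized use/availability weights W.

    Parameters
    ----------
    r : array-like
        Proportion of total cleaning time per species; non-negative,
        summing to 1 over cleaned species.
    p : array-like
        Availability proportion per species; non-negative, summing to 1.

    Returns
    -------
    ndarray
        W with ``W.sum() == 1``.

    Raises
    ------
    ValueError
        If shapes differ, entries are negative, or some species has
        ``r_i > 0`` with ``p_i == 0`` (use by an unavailable species is
        undefined without an availability floor; see
        :func:`station_selectivity`'s ``availability_floor``).
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape:
        raise ValueError(f"r and p must have equal length, got {r.shape} vs {p.shape}")
    if (r < 0).any() or (p < 0).any():
        raise ValueError("proportions must be non-negative")
    bad = (r > 0) & (p == 0)
    if bad.any():
        raise ValueError(
            "species used but unavailable (r>0, p=0) at indices "
            f"{np.flatnonzero(bad).tolist()}; supply an availability floor"
        )
    ratio = np.zeros_like(r)
    nz = p > 0
    ratio[nz] = r[nz] / p[nz]
    total = ratio.sum()
    if total == 0:
        raise ValueError("all use proportions are zero; W undefined")
    return ratio / total


def electivity_E(W, n: int):
    """Symmetric electivity E from weights W and cleaned-species richness n.

    ``E_i = (W_i - 1/n) / (W_i + 1/n)``; each value lies in [-1, 1], with
    0 meaning use proportional to availability.
    """
    if n < 1:
        raise ValueError("species richness n must be >= 1")
    W = np.asarray(W, dtype=float)
    if (W < 0).any() or (W > 1 + 1e-12).any():
        raise ValueError("W entries must lie in [0, 1]")
    inv_n = 1.0 / n
    return (W - inv_n) / (W + inv_n)


def _time_shares(cleans: pd.DataFrame, by: str) -> pd.Series:
    dur = (cleans["end_s"] - cleans["start_s"]).astype(float)
    if (dur < 0).any():
        bad = cleans.index[dur < 0].tolist()
        raise ValueError(f"clean events with end_s < start_s at rows {bad}")
    shares = dur.groupby(cleans[by]).sum()
    return shares


def station_selectivity(
    cleans: pd.DataFrame,
    frames: pd.DataFrame,
    *,
    grain: str = "species",
    availability_floor: float | None = None,
) -> SelectivityResult:
    """Electivity of one station-replicate survey.

    Time shares ``r`` come from summed clean durations per client
    species; availability ``p`` comes from distinct individuals per
    species in the frame censuses, renormalized over the union of
    cleaned and censused species.

    Parameters
    ----------
    cleans : DataFrame
        Clean events with ``start_s``, ``end_s``, ``client_species``,
        ``client_family`` columns (one survey).
    frames : DataFrame
        Frame-census records with ``individual_tag``, ``species``,
        ``family`` columns (same survey).
    grain : {"species", "family"}
        Taxonomic grain at which use and availability are tallied.
    availability_floor : float, optional
        Availability proportion assigned to species that were cleaned
        but never censused.  Default ``None`` raises instead (strict
        policy).

    Returns
    -------
    SelectivityResult
        ``station_value`` is NaN (with a flag) when the survey has no
        cleans or only zero-length cleans.
    """
    if grain not in ("species", "family"):
        raise ValueError(f"grain must be 'species' or 'family', got {grain!r}")
    use_col = "client_species" if grain == "species" else "client_family"
    avail_col = "species" if grain == "species" else "family"

    if len(cleans) == 0:
        return SelectivityResult([], np.array([]), np.array([]), np.nan, ["no_cleans"])

    shares = _time_shares(cleans, use_col)
    if shares.sum() == 0:
        return SelectivityResult(
            list(shares.index), np.array([]), np.array([]), np.nan, ["zero_length_cleans"]
        )
    shares = shares[shares > 0]
    cleaned = list(shares.index)
    n = len(cleaned)

    # availability: distinct tagged individuals per taxon
    if len(frames):
        counts = (
            frames.drop_duplicates("individual_tag").groupby(avail_col).size().astype(float)
        )
    else:
        counts = pd.Series(dtype=float)

    taxa = sorted(set(cleaned) | set(counts.index))
    flags: list[str] = []
    avail = counts.reindex(taxa).fillna(0.0)
    missing = [t for t in cleaned if avail[t] == 0]
    if missing:
        if availability_floor is None:
            raise ValueError(
                f"cleaned {grain} never censused: {missing}; "
                "set availability_floor to proceed"
            )
        avail[missing] = availability_floor
        flags.append("availability_floor_applied")

    p_full = (avail / avail.sum()).reindex(taxa)
    r_full = shares.reindex(taxa).fillna(0.0)
    r_full = r_full / r_full.sum()

    # E is computed over cleaned taxa only; p restricted and NOT renormalized
    # further, so availability of non-clients still dilutes preference.
    r = r_full[cleaned].to_numpy()
    p = p_full[cleaned].to_numpy()
    # r sums to 1 over cleaned taxa by construction
    W = electivity_W(r, p)
    E = electivity_E(W, n)
    if n == 1:
        flags.append("single_species")
    return SelectivityResult(cleaned, W, E, float(E.mean()), flags)
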