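"""Dung removal rates from pat weights, with evaporation correction.

Each experimental pat starts at a known wet weight ``IWwet`` (nominally
300 g) and is recovered after 48 h with a final wet weight ``FWwet`` and,
after oven-drying, a final dry weight ``FWdry``.  Because dung loses water
in the field, removal is computed on the dry-mass scale:

    WP    = (FWwet - FWdry) / FWwet          water proportion
    IWdry = IWwet * (1 - WP)                 estimated initial dry mass
    DRR   = IWdry - FWdry                    dry mass removed in 48 h

``WP`` can be taken from each experimental pat's own final weights
(``mode="unit"``) or — the default — from the mesh-covered control pats at
the same pasture, which evaporate but cannot be worked by beetles
(``mode="control"``).  Negative rates (e.g. mass gain after rain) are
returned unclamped and flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import StudyBundle

__all__ = ["water_proportion", "removal_rate", "site_removal", "removal_table"]


class RemovalConfigError(ValueError):
    """Requested WP mode cannot be applied to the available pats."""


def water_proportion(fw_wet, fw_dry):
    """Water proportion of a pat from its final wet and dry weights.

    Accepts scalars or arrays; returns a fraction in [0, 1].
    """
    fw_wet = np.asarray(fw_wet, dtype=float)
    fw_dry = np.asarray(fw_dry, dtype=float)
    if np.any(fw_wet <= 0):
        raise ValueError("final wet weight must be > 0 to define a water proportion")
    if np.any(fw_dry < 0) or np.any(fw_dry > fw_wet):
        raise ValueError("final dry weight must lie in [0, final wet weight]")
    wp = (fw_wet - fw_dry) / fw_wet
    return wp if wp.ndim else float(wp)


def removal_rate(iw_wet, fw_dry, wp):
    """Dry-mass removal: ``IWwet * (1 - WP) - FWdry``.

    Negative values (apparent mass gain) are returned unclamped.
    """
    iw_wet = np.asarray(iw_wet, dtype=float)
    fw_dry = np.asarray(fw_dry, dtype=float)
    wp = np.asarray(wp, dtype=float)
    if np.any(iw_wet <= 0):
        raise ValueError("initial wet weight must be > 0")
    if np.any((wp < 0) | (wp > 1)):
        raise ValueError("water proportion must lie in [0, 1]")
    if np.any(fw_dry < 0):
        raise ValueError("final dry weight must be >= 0")
    drr = iw_wet * (1.0 - wp) - fw_dry
    return drr if drr.ndim else float(drr)


def site_removal(units: pd.DataFrame, mode: str = "control",
                 clamp_negative: bool = False) -> tuple[pd.DataFrame, dict]:
    """Per-unit removal results and a site summary for one pasture.

    Parameters
    ----------
    units
        Dung-pat rows of a single site-regime (columns as in
        ``dungpats.csv``: ``unit_id``, ``role``, ``iw_wet``, ``fw_wet``,
        ``fw_dry``).
    mode
        ``"unit"`` applies each experimental pat's own water proportion;
        ``"control"`` (default) uses the mean water proportion over the
        site's control pats for every experimental pat.
    clamp_negative
        Clamp negative rates to zero instead of retaining them.

    Returns
    -------
    (results, summary)
        ``results`` has one row per experimental unit with ``wp``,
        ``iw_dry``, ``drr`` and a ``negative`` flag; ``summary`` holds the
        mean, sample SD (n-1) and count of ``drr``.
    """
    if mode not in ("unit", "control"):
        raise ValueError(f"unknown WP mode {mode!r}")
    exp = units[units["role"] == "experimental"]
    if exp.empty:
        raise RemovalConfigError("site has no experimental dung pats")
    if mode == "control":
        ctl = units[units["role"] == "control"]
        if ctl.empty:
            raise RemovalConfigError(
                "WP mode 'control' requires at least one control pat at the site")
        wp = np.full(len(exp), float(np.mean(
            water_proportion(ctl["fw_wet"].to_numpy(), ctl["fw_dry"].to_numpy()))))
    else:
        wp = water_proportion(exp["fw_wet"].to_numpy(), exp["fw_dry"].to_numpy())
    iw_dry = exp["iw_wet"].to_numpy(dtype=float) * (1.0 - wp)
    drr = removal_rate(exp["iw_wet"].to_numpy(), exp["fw_dry"].to_numpy(), wp)
    drr = np.atleast_1d(drr)
    negative = drr < 0
    if clamp_negative:
        drr = np.maximum(drr, 0.0)
    results = pd.DataFrame({
        "unit_id": exp["unit_id"].to_numpy(),
        "wp": np.atleast_1d(wp),
        "iw_dry": iw_dry,
        "drr": drr,
        "negative": negative,
    })
    summary = {
        "mean_drr": float(np.mean(drr)),
        "sd_drr": float(np.std(drr, ddof=1)) if len(drr) > 1 else 0.0,
        "n": int(len(drr)),
        "n_negative": int(negative.sum()),
    }
    return results, summary


def removal_table(bundle: StudyBundle, mode: str = "control",
                  clamp_negative: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply :func:`site_removal` to every pasture of a study bundle.

    Returns the unit-level removal table and the per-site summary table
    (``site_id``, ``regime``, ``mean_drr``, ``sd_drr``, ``n``).
    """
    unit_frames, summaries = [], []
    regime_of = bundle.sites.set_index("site_id")["regime"]
    for site_id, units in bundle.dungpats.groupby("site_id", sort=True):
        results, summary = site_removal(units, mode=mode,
                                        clamp_negative=clamp_negative)
        results.insert(0, "site_id", site_id)
        results.insert(1, "regime", regime_of[site_id])
        unit_frames.append(results)
        summaries.append({"site_id": site_id, "regime": regime_of[site_id], **summary})
    return (pd.concat(unit_frames, ignore_index=True),
            pd.DataFrame(summaries))
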