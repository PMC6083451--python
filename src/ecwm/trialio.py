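"""Trial-table CSV format, curve export, and run configuration.

Files store angles in stimulus degrees on the [-90, 90) scale; everything
internal is mapped radians.  The trial CSV header is::

    subject,condition,block,set_size,target_deg,nontargets_deg,response_deg

with ``nontargets_deg`` a semicolon-separated list (empty for set size 1).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from ecwm.orientation import H_BIAS, H_PRECISION, deg_to_rad, rad_to_deg
from ecwm.synthetic import TRIAL_COLUMNS

CSV_COLUMNS = ["subject", "condition", "block", "set_size",
               "target_deg", "nontargets_deg", "response_deg"]


class TrialTableError(ValueError):
    """Malformed trial-table content; carries the offending line number."""


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table (radians, internal layout) to degree-based CSV."""
    out = pd.DataFrame({
        "subject": trials["subject"],
        "condition": trials["condition"],
        "block": trials["block"].astype(int),
        "set_size": trials["set_size"].astype(int),
        "target_deg": rad_to_deg(trials["target"].to_numpy()),
        "nontargets_deg": [
            ";".join(f"{v:.9f}" for v in rad_to_deg(np.asarray(nt, dtype=float)))
            for nt in trials["nontargets"]
        ],
        "response_deg": rad_to_deg(trials["response"].to_numpy()),
    })
    out.to_csv(path, index=False, float_format="%.9f")


def read_trials(path) -> pd.DataFrame:
    """Read a degree-based trial CSV into the internal radian layout.

    Raises
    ------
    TrialTableError
        Naming the 1-based data line number of the first malformed row.
    """
    df = pd.read_csv(path, dtype={"subject": str, "condition": str},
                     keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            set_size = int(row.set_size)
            target = float(row.target_deg)
            response = float(row.response_deg)
            raw = str(row.nontargets_deg).strip()
            nts = ([float(v) for v in raw.split(";")] if raw else [])
            if not -90.0 <= target < 90.0 or not -90.0 <= response < 90.0:
                raise ValueError("angles must lie in [-90, 90)")
            if len(nts) != set_size - 1:
                raise ValueError(
                    f"expected {set_size - 1} nontargets, got {len(nts)}")
        except (TypeError, ValueError) as exc:
            raise TrialTableError(f"line {i}: {exc}") from exc
        records.append({
            "subject": row.subject,
            "condition": row.condition,
            "block": int(row.block),
            "set_size": set_size,
            "target": float(deg_to_rad(target)),
            "nontargets": deg_to_rad(np.array(nts, dtype=float)),
            "response": float(deg_to_rad(response)),
        })
    return pd.DataFrame(records, columns=TRIAL_COLUMNS)


def write_curves(curves: dict, path) -> None:
    """Export smoothed curves as CSV.

    ``curves`` maps a label (e.g. set size) to a dict with ``points``
    (radians), ``bias`` (radians), ``precision`` (1/rad^2) and optionally
    ``n_effective`` arrays.
    """
    frames = []
    for label, c in curves.items():
        pts = np.asarray(c["points"])
        frames.append(pd.DataFrame({
            "label": label,
            "orientation_deg": rad_to_deg(pts),
            "bias_deg": rad_to_deg(np.asarray(c["bias"])) if "bias" in c else np.nan,
            "precision_rad2": c.get("precision", np.full(len(pts), np.nan)),
            "n_effective": c.get("n_effective", np.full(len(pts), np.nan)),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fit_result(fit, path) -> None:
    """Serialize a FitResult to JSON."""
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "model": {
        "family": "neural",
        "M": 100,
        "kappa": 2.0,
        "gamma": 50.0,
        "prior": "natural_cardinal",
        # SPA parameters (used when family == "spa")
        "K": 3,
        "kappa1": 5.0,
        "eta": 0.0,
        "lam": 0.0,
    },
    "fit": {
        "grid": "coarse",
        "reps": 10000,
        "J": 25,
        "Q": 25,
        "n_grid": 100,
    },
    "smoothing": {
        "h_bias": H_BIAS,
        "h_precision": H_PRECISION,
    },
    "experiment": {
        "n_blocks": 8,
        "trials_per_block": 72,
        "set_size": 4,
        "condition": "incongruent",
    },
    "simulate": {
        "set_sizes": [1, 2, 4, 8],
        "trials_per_size": 225,
    },
}


def _merge_strict(defaults, override, path=""):
    out = dict(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise KeyError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config section {path}{key} must be a mapping")
            out[key] = _merge_strict(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Load a YAML run config, validated against the default schema.

    Unknown keys raise (no silent defaults); omitted keys fall back to the
    reference settings (M=100, J=Q=25, reps=10^4, h=0.61/0.23).
    """
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise TypeError("config root must be a mapping")
    return _merge_strict(DEFAULT_CONFIG, user)


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def model_from_config(cfg: dict):
    """Instantiate the generative model described by a config block."""
    from ecwm.neural import PopulationConfig
    from ecwm.priors import Prior
    from ecwm.spa import SPAParams

    m = cfg["model"]
    if m["family"] == "neural":
        return PopulationConfig(M=int(m["M"]), kappa=float(m["kappa"]),
                                gamma=float(m["gamma"]),
                                prior=Prior(m["prior"]))
    if m["family"] == "spa":
        return SPAParams(K=int(m["K"]), kappa1=float(m["kappa1"]),
                         eta=float(m["eta"]), lam=float(m["lam"]))
    raise ValueError(f"unknown model family: {m['family']!r}")
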