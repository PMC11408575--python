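"""Plain-file readers/writers so every pipeline stage is resumable.

An epoch bundle on disk is one CSV matrix (``n_time × n_chan``) per trial plus
one JSON sidecar per subject/condition::

    {"subject": "S1", "condition": "Cond1", "channels": [...], "sfreq": 500.0,
     "times": [...], "trial_files": ["S1_Cond1_trial000.csv", ...]}

Adapters for standard EEG epoch formats (BrainVision, EDF, EEGLAB SET) are
interface stubs: implement :func:`read_external` for a concrete backend.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import EpochSet, TemplateMap, validate_epochset

__all__ = [
    "write_epoch_bundle",
    "read_epoch_bundle",
    "write_score_table",
    "read_score_table",
    "write_template",
    "read_template",
    "read_external",
]

_SIDECAR_KEYS = {"subject", "condition", "channels", "sfreq", "times",
                 "trial_files"}


def write_epoch_bundle(epochsets: list[EpochSet], out_dir: str | Path) -> list[Path]:
    """Write epoch bundles; returns the sidecar paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecars = []
    for e in epochsets:
        stem = f"{e.subject_id}_{e.condition}"
        files = []
        for i, tr in enumerate(e.trials):
            f = f"{stem}_trial{i:03d}.csv"
            np.savetxt(out / f, tr, delimiter=",", fmt="%.6f")
            files.append(f)
        sidecar = out / f"{stem}.json"
        sidecar.write_text(json.dumps({
            "subject": e.subject_id, "condition": e.condition,
            "channels": e.channels, "sfreq": e.sfreq,
            "times": e.times.tolist(), "trial_files": files,
        }))
        sidecars.append(sidecar)
    return sidecars


def read_epoch_bundle(path: str | Path) -> list[EpochSet]:
    """Read every sidecar JSON under ``path`` (or a single sidecar file)."""
    p = Path(path)
    sidecars = [p] if p.is_file() else sorted(p.glob("*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no epoch sidecars found under {p}")
    out = []
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        missing = _SIDECAR_KEYS - meta.keys()
        if missing:
            raise ValueError(f"{sc}: sidecar missing keys {sorted(missing)}")
        extra = meta.keys() - _SIDECAR_KEYS
        if extra:
            warnings.warn(f"{sc}: ignoring unknown sidecar keys {sorted(extra)}")
        trials = []
        for f in meta["trial_files"]:
            fp = sc.parent / f
            if not fp.exists():
                raise FileNotFoundError(f"{sc}: trial file {f} not found")
            trials.append(np.loadtxt(fp, delimiter=",", ndmin=2))
        e = EpochSet(subject_id=meta["subject"], condition=meta["condition"],
                     trials=trials, times=np.asarray(meta["times"], float),
                     channels=list(meta["channels"]), sfreq=float(meta["sfreq"]))
        problems = validate_epochset(e)
        if problems:
            raise ValueError(f"{sc}: invalid epoch set: {problems}")
        out.append(e)
    return out


def write_score_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a score table with Mean and SD footer rows over the numeric columns."""
    if df.empty:
        raise ValueError("score table is empty")
    num = df.select_dtypes("number")
    footer = pd.DataFrame([num.mean(), num.std(ddof=0) if len(df) == 1 else num.std(ddof=1)])
    footer.insert(0, "Subj_ID", ["Mean", "SD"])
    out = pd.concat([df, footer], ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a score table, dropping the Mean/SD footer rows."""
    df = pd.read_csv(path)
    return df[~df["Subj_ID"].isin(["Mean", "SD"])].reset_index(drop=True)


def write_template(tpl: TemplateMap, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "name": tpl.name, "topography": tpl.topography.tolist(),
        "interval": list(tpl.interval), "site": tpl.site,
    }))
    return path


def read_template(path: str | Path) -> TemplateMap:
    meta = json.loads(Path(path).read_text())
    return TemplateMap(name=meta["name"],
                       topography=np.asarray(meta["topography"], float),
                       interval=tuple(meta["interval"]), site=meta["site"])


def read_external(path: str | Path, fmt: str) -> list[EpochSet]:
    """Adapter hook for standard EEG epoch formats (not implemented here)."""
    raise NotImplementedError(
        f"no reader registered for format {fmt!r}; convert epochs to the CSV "
        "bundle layout (see write_epoch_bundle) instead")
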