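#!/usr/bin/env python
"""Convert externally exported IMU trial files into the package's CSV dialect.

The study recordings are distributed as vendor-software exports whose exact
column layout varies; this script is a column-mapping template, not a tested
parser.  A YAML config names, per logical channel, the source column (and
optional unit scale), plus the trial/task/location labels:

.. code-block:: yaml

    fs: 60.0
    aligned: false
    columns:
      time_s: {name: "PacketCounter", scale: 0.0166667}   # or a time column
      acc_x: {name: "Acc_X"}
      acc_y: {name: "Acc_Y"}
      acc_z: {name: "Acc_Z"}
      gyr_x: {name: "Gyr_X", scale: 57.29578}   # rad/s -> deg/s
      gyr_y: {name: "Gyr_Y", scale: 57.29578}
      gyr_z: {name: "Gyr_Z", scale: 57.29578}
    trials:
      - trial_id: subj01_straight_01
        task: straight
        location: DFoot
        source: raw/subj01/straight_01_DFoot.txt
        ref_events_csv: converted/subj01_straight_01_ref.csv
        calib_stand_source: raw/subj01/stand_DFoot.txt
        calib_sit_source: raw/subj01/sit_DFoot.txt

Reference HS/TO events must already be in the event dialect (``t_s,kind``).
Usage::

    python scripts/convert_dataset.py config.yaml --out data/deposited
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd
import yaml

from imugait.signal_model import IMU_CSV_COLUMNS


def _convert_file(src: Path, columns: dict, fs: float, dst: Path) -> None:
    sep = "\t" if src.suffix.lower() in (".txt", ".tsv") else ","
    raw = pd.read_csv(src, sep=sep, comment="/")
    out = {}
    for target in IMU_CSV_COLUMNS:
        spec = columns.get(target)
        if spec is None:
            if target != "time_s":
                raise SystemExit(f"{src}: no mapping for column {target}")
            out[target] = pd.RangeIndex(len(raw)).to_numpy() / fs
            continue
        series = raw[spec["name"]].astype(float) * float(spec.get("scale", 1.0))
        out[target] = series.to_numpy()
    dst.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(out)[IMU_CSV_COLUMNS].to_csv(dst, index=False, float_format="%.9f")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("config", type=Path)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()
    cfg = yaml.safe_load(args.config.read_text())
    base = args.config.parent
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    fs = float(cfg.get("fs", 60.0))
    entries = []
    for trial in cfg["trials"]:
        entry = {
            "trial_id": trial["trial_id"],
            "task": trial["task"],
            "location": trial["location"],
            "frame": trial.get("frame", "sensor"),
            "ref_events_csv": trial["ref_events_csv"],
        }
        stem = f"{trial['trial_id']}_{trial['location']}"
        _convert_file(base / trial["source"], cfg["columns"], fs, out / f"{stem}.csv")
        entry["imu_csv"] = f"{stem}.csv"
        for key in ("calib_stand", "calib_sit"):
            src = trial.get(f"{key}_source")
            if src:
                _convert_file(base / src, cfg["columns"], fs, out / f"{stem}_{key}.csv")
                entry[f"{key}_csv"] = f"{stem}_{key}.csv"
        entries.append(entry)
    manifest = {
        "fs": fs,
        "aligned": bool(cfg.get("aligned", False)),
        "trials": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"wrote {len(entries)} trials and {out / 'manifest.json'}")


if __name__ == "__main__":
    main()
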