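"""Readers and writers for every file dialect of the pipeline.

All files are UTF-8 text with a header row and '.' decimal separator.
Readers validate schemas strictly and name the file, column and (where
sensible) row of every problem; write -> read round trips are
value-identical.  On disk, regions use anatomical left/right names plus a
per-participant lesion side; loaders remap to the lesion-relative canonical
frame used in memory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import edge_labels
from .grip import DigitForceTrial, GripError
from .regions import anatomical_name, anatomical_to_canonical, canonical_name
from .simulate import CohortData, CohortSpec, GroundTruth

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["time_s", "digit", "fn_N", "ft1_N", "ft2_N"]
META_COLUMNS = ["participant", "hand", "trial_kind", "repetition", "cue_grip_s", "cue_rest_s", "file"]
REGION_COLUMNS = ["name", "left_right", "class", "volume_mm3"]
LESION_COLUMNS = ["participant", "region", "lesion_fraction"]


class IOValidationError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOValidationError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    try:
        vals = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        line = int(bad.index[0]) + 2 if len(bad) else "?"
        raise IOValidationError(f"{path}: non-numeric value in column {col!r} near line {line}") from exc
    return vals


# ---------------------------------------------------------------- trials

def write_trial_csv(trial: DigitForceTrial, path) -> None:
    frames = []
    for digit, arr in trial.forces.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": trial.time,
                    "digit": digit,
                    "fn_N": arr[:, 0],
                    "ft1_N": arr[:, 1],
                    "ft2_N": arr[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_trial_csv(path, sampling_rate: float, cue_grip: float, cue_rest: float | None,
                   trial_kind: str, hand: str, participant: str = "", repetition: int = 0) -> DigitForceTrial:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise IOValidationError(f"{path}: empty trial file")
    _require_columns(df, TRIAL_COLUMNS, path)
    forces = {}
    time = None
    for digit, sub in df.groupby("digit", sort=True):
        t = _numeric(sub, "time_s", path)
        cols = np.column_stack([_numeric(sub, c, path) for c in ("fn_N", "ft1_N", "ft2_N")])
        if time is None:
            time = t
        elif t.shape != time.shape or not np.array_equal(t, time):
            raise IOValidationError(f"{path}: digits have inconsistent time axes")
        forces[str(digit)] = cols
    try:
        return DigitForceTrial(
            sampling_rate=sampling_rate,
            time=time,
            forces=forces,
            cue_grip=cue_grip,
            cue_rest=cue_rest,
            trial_kind=trial_kind,
            hand=hand,
            participant=participant,
            repetition=repetition,
        )
    except GripError as exc:
        raise IOValidationError(f"{path}: {exc}") from exc


def write_trials(trials: dict[str, list[DigitForceTrial]], out_dir) -> Path:
    """Write one CSV per trial plus the trial-metadata CSV; returns meta path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for participant in sorted(trials):
        for trial in trials[participant]:
            fname = f"{participant}_{trial.hand}_{trial.trial_kind}_{trial.repetition}.csv"
            write_trial_csv(trial, out_dir / fname)
            rows.append(
                {
                    "participant": participant,
                    "hand": trial.hand,
                    "trial_kind": trial.trial_kind,
                    "repetition": trial.repetition,
                    "cue_grip_s": trial.cue_grip,
                    "cue_rest_s": "" if trial.cue_rest is None else trial.cue_rest,
                    "file": fname,
                    "sampling_rate_hz": trial.sampling_rate,
                }
            )
    meta_path = out_dir / "trial_meta.csv"
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path


def read_trials(meta_path, trials_dir=None) -> dict[str, list[DigitForceTrial]]:
    meta_path = Path(meta_path)
    trials_dir = Path(trials_dir) if trials_dir is not None else meta_path.parent
    meta = pd.read_csv(meta_path)
    _require_columns(meta, META_COLUMNS, meta_path)
    out: dict[str, list[DigitForceTrial]] = {}
    for i, row in meta.iterrows():
        cue_rest = row["cue_rest_s"]
        cue_rest = None if pd.isna(cue_rest) or cue_rest == "" else float(cue_rest)
        fs = float(row.get("sampling_rate_hz", 500.0))
        trial = read_trial_csv(
            trials_dir / str(row["file"]),
            sampling_rate=fs,
            cue_grip=float(row["cue_grip_s"]),
            cue_rest=cue_rest,
            trial_kind=str(row["trial_kind"]),
            hand=str(row["hand"]),
            participant=str(row["participant"]),
            repetition=int(row["repetition"]),
        )
        out.setdefault(str(row["participant"]), []).append(trial)
    if not out:
        raise IOValidationError(f"{meta_path}: no trials listed")
    return out


# ---------------------------------------------------------------- matrices

def write_square_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_square_tsv(path, what: str = "matrix", nonnegative: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty:
        raise IOValidationError(f"{path}: empty {what}")
    if list(df.index) != list(df.columns):
        raise IOValidationError(f"{path}: {what} must be square with matching row/column names")
    try:
        vals = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise IOValidationError(f"{path}: {what} contains non-numeric cells") from exc
    if not np.all(np.isfinite(vals)):
        i, j = np.argwhere(~np.isfinite(vals))[0]
        raise IOValidationError(f"{path}: non-finite value at row {df.index[i]!r}, column {df.columns[j]!r}")
    if nonnegative and np.any(vals < 0):
        i, j = np.argwhere(vals < 0)[0]
        raise IOValidationError(f"{path}: negative value at row {df.index[i]!r}, column {df.columns[j]!r}")
    return df.astype(float)


# ---------------------------------------------------------------- metadata

def write_regions_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_regions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, REGION_COLUMNS, path)
    vols = _numeric(df, "volume_mm3", path)
    if np.any(vols <= 0):
        bad = df.loc[vols <= 0, "name"].iloc[0]
        raise IOValidationError(f"{path}: region {bad!r} has non-positive volume")
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise IOValidationError(f"{path}: duplicate region name {dup!r}")
    return df


def write_participants_csv(sides: pd.Series, path) -> None:
    pd.DataFrame({"participant": sides.index, "lesion_side": sides.to_numpy()}).to_csv(path, index=False)


def read_participants_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    _require_columns(df, ["participant", "lesion_side"], path)
    bad = df[~df["lesion_side"].isin(["left", "right"])]
    if len(bad):
        raise IOValidationError(
            f"{path}: lesion_side must be 'left'/'right', got {bad['lesion_side'].iloc[0]!r} "
            f"for participant {bad['participant'].iloc[0]!r}"
        )
    return pd.Series(df["lesion_side"].to_numpy(), index=df["participant"].astype(str), name="lesion_side")


def write_lesions_csv(fractions: pd.DataFrame, sides: pd.Series, path) -> None:
    """Participants x canonical-regions fractions -> long anatomical CSV."""
    rows = []
    for participant, row in fractions.iterrows():
        side = sides[participant]
        for region, val in row.items():
            rows.append((participant, anatomical_name(region, side), val))
    pd.DataFrame(rows, columns=LESION_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_lesions_csv(path, sides: pd.Series, region_names: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, LESION_COLUMNS, path)
    vals = _numeric(df, "lesion_fraction", path)
    if np.any((vals < 0) | (vals > 1)):
        i = int(np.argwhere((vals < 0) | (vals > 1))[0][0])
        raise IOValidationError(
            f"{path}: lesion_fraction out of [0,1] near line {i + 2} "
            f"(participant {df['participant'].iloc[i]!r}, region {df['region'].iloc[i]!r})"
        )
    out = pd.DataFrame(index=sorted(df["participant"].astype(str).unique()), columns=region_names, dtype=float)
    for _, row in df.iterrows():
        p = str(row["participant"])
        if p not in sides.index:
            raise IOValidationError(f"{path}: participant {p!r} has no lesion_side entry")
        canon = canonical_name(str(row["region"]), sides[p])
        if canon not in region_names:
            raise IOValidationError(f"{path}: unknown region {row['region']!r} (participant {p!r})")
        out.at[p, canon] = float(row["lesion_fraction"])
    if out.isna().any().any():
        p = out.index[out.isna().any(axis=1)][0]
        missing = out.columns[out.loc[p].isna()].tolist()
        raise IOValidationError(f"{path}: participant {p!r} missing lesion fractions for {missing[:5]}")
    return out


# ---------------------------------------------------------------- tables

def write_edge_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, float_format="%.17g")


def read_edge_table(path, regions: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.empty:
        raise IOValidationError(f"{path}: empty edge table")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise IOValidationError(f"{path}: edge table contains non-numeric cells") from exc
    if regions is not None:
        expected = edge_labels(regions)
        if list(df.columns) != expected:
            raise IOValidationError(f"{path}: edge columns do not match the region set")
    df.index = df.index.astype(str)
    df.index.name = "participant"
    return df


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    scores.rename_axis("participant").to_csv(path, float_format="%.17g")


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.empty:
        raise IOValidationError(f"{path}: empty scores table")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise IOValidationError(f"{path}: scores contain non-numeric cells") from exc
    df.index = df.index.astype(str)
    return df


def write_measures_csv(ratios: pd.DataFrame, path) -> None:
    ratios.rename_axis("participant").to_csv(path, float_format="%.17g")


read_measures_csv = read_scores_csv


def write_loadings_csv(loadings_long: pd.DataFrame, path) -> None:
    loadings_long.to_csv(path, index=False)


def write_association_csv(cells: pd.DataFrame, path) -> None:
    cols = ["network", "measure", "partial_r", "beta", "se", "p_value", "simple_r",
            "vif_score", "vif_lesion", "n", "best_flag"]
    cells[cols].to_csv(path, index=False)


def read_association_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["network", "measure", "partial_r", "beta", "se", "simple_r"], path)
    return df


# ---------------------------------------------------------------- json

def _df_payload(df: pd.DataFrame) -> dict:
    return {
        "index": [str(i) for i in df.index],
        "columns": [str(c) for c in df.columns],
        "data": df.to_numpy(dtype=float).tolist(),
    }


def _df_from_payload(payload: dict) -> pd.DataFrame:
    return pd.DataFrame(payload["data"], index=payload["index"], columns=payload["columns"])


def write_json(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_ground_truth(truth: GroundTruth, path) -> None:
    write_json(
        {
            "latent_scores": _df_payload(truth.latent_scores),
            "pattern": _df_payload(truth.pattern),
            "effects": _df_payload(truth.effects),
            "lesion_latents": _df_payload(truth.lesion_latents),
            "true_ratios": _df_payload(truth.true_ratios),
            "paretic_true": _df_payload(truth.paretic_true),
            "nonparetic_true": _df_payload(truth.nonparetic_true),
        },
        path,
    )


def read_ground_truth(path) -> GroundTruth:
    data = read_json(path)
    return GroundTruth(**{k: _df_from_payload(v) for k, v in data.items()})


# ---------------------------------------------------------------- cohort bundle

def write_cohort(cohort: CohortData, out_dir) -> None:
    """Write every file the CLI stages consume, in anatomical naming."""
    from .regions import default_anatomical_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort.trials:
        write_trials(cohort.trials, out_dir / "trials")
    counts_dir = out_dir / "counts"
    counts_dir.mkdir(exist_ok=True)
    for participant, matrix in cohort.raw_counts.items():
        side = cohort.lesion_sides[participant]
        anat = matrix.rename(
            index=lambda r: anatomical_name(r, side), columns=lambda r: anatomical_name(r, side)
        )
        anat = anat.sort_index(axis=0).sort_index(axis=1)
        write_square_tsv(anat, counts_dir / f"{participant}.tsv")
    anat_table = default_anatomical_table(cohort.regions)
    write_regions_csv(anat_table, out_dir / "regions.csv")
    anat_dist = cohort.distances.rename(
        index=lambda r: anatomical_name(r, "left"), columns=lambda r: anatomical_name(r, "left")
    ).sort_index(axis=0).sort_index(axis=1)
    write_square_tsv(anat_dist, out_dir / "distances.tsv")
    write_participants_csv(cohort.lesion_sides, out_dir / "participants.csv")
    write_lesions_csv(cohort.lesion_fractions, cohort.lesion_sides, out_dir / "lesions.csv")
    if cohort.truth is not None:
        write_ground_truth(cohort.truth, out_dir / "ground_truth.json")


def read_cohort(in_dir, spec: CohortSpec | None = None) -> CohortData:
    """Load a cohort bundle back into the canonical in-memory form."""
    from .regions import default_regions

    in_dir = Path(in_dir)
    spec = spec or CohortSpec()
    sides = read_participants_csv(in_dir / "participants.csv")
    regions = default_regions()
    names = [r.name for r in regions]
    read_regions_csv(in_dir / "regions.csv")  # validated; volumes are canonical defaults
    dist_anat = read_square_tsv(in_dir / "distances.tsv", "distance matrix", nonnegative=True)
    distances = anatomical_to_canonical(dist_anat, "left").loc[names, names]
    counts = {}
    for participant in sides.index:
        path = in_dir / "counts" / f"{participant}.tsv"
        if not path.exists():
            raise IOValidationError(f"{path}: missing streamline counts for participant {participant!r}")
        raw = read_square_tsv(path, "streamline counts", nonnegative=True)
        counts[participant] = anatomical_to_canonical(raw, sides[participant]).loc[names, names]
    lesions = read_lesions_csv(in_dir / "lesions.csv", sides, names)
    trials = {}
    meta_path = in_dir / "trials" / "trial_meta.csv"
    if meta_path.exists():
        trials = read_trials(meta_path)
    truth = None
    gt_path = in_dir / "ground_truth.json"
    if gt_path.exists():
        truth = read_ground_truth(gt_path)
    return CohortData(
        spec=spec,
        participants=list(sides.index),
        regions=regions,
        distances=distances,
        raw_counts=counts,
        lesion_fractions=lesions.loc[list(sides.index)],
        lesion_sides=sides,
        trials=trials,
        truth=truth,
    )
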