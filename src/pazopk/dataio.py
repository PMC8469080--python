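"""NONMEM-style CSV dataset reader/writer.

One row per event: dose rows (EVID=1) carry AMT, SS and II; observation
rows (EVID=0) carry DV and the BLQ flag.  Missing values are written as
"." (the pharmacometric convention).  Occasions are encoded in OCC and
each occasion has exactly one dose row whose TIME anchors the
observation times of that occasion (obs TIME = dose TIME + time after
dose).  Steady-state occasions are written SS=1 and read back as the
package's canonical steady-state marker; ground-truth simulation fields
are not serialised.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import COVARIATE_NAMES, Cohort, SS_N_DOSES, Subject
from .model import DoseRegimen

__all__ = ["DATASET_COLUMNS", "read_dataset", "write_dataset"]

DATASET_COLUMNS = (
    "ID", "TIME", "TAD", "EVID", "MDV", "AMT", "SS", "II", "DV", "BLQ", "OCC",
    "ASAT", "ALAT", "ALB", "CREAT", "AGE", "SEX", "FOOD", "DOSE_DAILY",
)


class DatasetError(ValueError):
    """Schema or content problem in a dataset file."""


def write_dataset(cohort: Cohort, path) -> None:
    rows = []
    for s in cohort.subjects:
        for occ in s.occasions:
            reg = s.regimens[occ]
            start = s.occasion_start[occ]
            covs = {name: s.covariates.get(name, {}).get(occ, float("nan"))
                    for name in COVARIATE_NAMES}
            rows.append({
                "ID": s.id, "TIME": start, "TAD": 0.0, "EVID": 1, "MDV": 1,
                "AMT": reg.dose, "SS": 1 if reg.steady_state else 0,
                "II": reg.tau, "DV": float("nan"), "BLQ": 0, "OCC": occ,
                **covs, "DOSE_DAILY": reg.daily_dose,
            })
            for j in np.where(np.asarray(s.obs_occ) == occ)[0]:
                rows.append({
                    "ID": s.id, "TIME": start + s.obs_time[j],
                    "TAD": s.obs_time[j], "EVID": 0,
                    "MDV": 0, "AMT": float("nan"), "SS": float("nan"),
                    "II": float("nan"), "DV": s.obs_conc[j],
                    "BLQ": int(s.obs_blq[j]), "OCC": occ,
                    **covs, "DOSE_DAILY": reg.daily_dose,
                })
    frame = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    # %.17g guarantees binary round-trip of every float through the CSV
    frame.to_csv(path, index=False, na_rep=".", float_format="%.17g")


def read_dataset(path) -> Cohort:
    frame = pd.read_csv(path, na_values=["."], dtype={"ID": str, "OCC": str},
                        float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"dataset is missing mandatory column(s): {missing}")

    subjects = []
    for sid, grp in frame.groupby("ID", sort=False):
        grp = grp.reset_index()
        times = grp["TIME"].to_numpy(float)
        if np.any(np.diff(times) < 0):
            bad = int(grp.loc[np.where(np.diff(times) < 0)[0][0] + 1, "index"]) + 2
            raise DatasetError(
                f"TIME not non-decreasing for subject {sid} (file line {bad})")
        doses = grp[grp["EVID"] == 1]
        obs = grp[grp["EVID"] == 0]
        if doses.empty:
            raise DatasetError(f"subject {sid} has no dose row")
        bad_obs = obs[obs["DV"].isna() & (obs["BLQ"] != 1)]
        if not bad_obs.empty:
            line = int(bad_obs.iloc[0]["index"]) + 2
            raise DatasetError(
                f"observation row without DV and not BLQ for subject {sid} "
                f"(file line {line})")

        regimens, start, covariates = {}, {}, {n: {} for n in COVARIATE_NAMES}
        for _, row in doses.iterrows():
            occ = row["OCC"]
            if occ in regimens:
                raise DatasetError(f"duplicate dose row for {sid}/{occ}")
            regimens[occ] = DoseRegimen(
                dose=float(row["AMT"]), tau=float(row["II"]),
                n_doses_before_obs=SS_N_DOSES if row["SS"] == 1 else 1,
                occasion=occ)
            start[occ] = float(row["TIME"])
            for name in COVARIATE_NAMES:
                v = row[name]
                covariates[name][occ] = float(v) if not pd.isna(v) else float("nan")

        obs_occ, obs_time, obs_conc, obs_blq = [], [], [], []
        for _, row in obs.iterrows():
            occ = row["OCC"]
            if occ not in regimens:
                raise DatasetError(
                    f"observation in occasion {occ!r} of subject {sid} has no dose row")
            tad = row["TAD"]
            if pd.isna(tad) or tad < 0:
                raise DatasetError(
                    f"observation without valid TAD for subject {sid}")
            obs_occ.append(occ)
            obs_time.append(float(tad))
            dv = row["DV"]
            obs_conc.append(float(dv) if not pd.isna(dv) else float("nan"))
            obs_blq.append(bool(row["BLQ"] == 1))

        arm = "rich" if str(sid).startswith("R") else "tdm"
        subjects.append(Subject(
            id=str(sid), arm=arm, regimens=regimens, occasion_start=start,
            covariates=covariates, obs_occ=obs_occ,
            obs_time=np.asarray(obs_time, float),
            obs_conc=np.asarray(obs_conc, float),
            obs_blq=np.asarray(obs_blq, bool)))
    return Cohort(subjects=subjects)
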