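"""Recording containers and tidy-CSV metric exchange.

Native container: one HDF5 file per cohort with the layout

    /<subject_id>/
        protocol/{levels, start_times, end_times}   (+ transition, baseline attrs)
        ecg/rpeaks
        map/{time, value}
        pleth/{time, value}
        eit/<site>/{time, values, channel_valid}
        eis/<site>/{time, freqs, z_real, z_imag}
        lbnp/{time, level}

Mixed-rate channels (40 Hz waveforms next to one-spectrum-per-minute EIS)
make a hierarchical container the natural native format; a flat per-channel
CSV export of the same content is provided for interoperability, and the
``csvdir`` read dialect loads it back.  The ``zenodo`` dialect is a thin
adapter aimed at publicly deposited LBNP recordings; its layout mapping is
isolated here so that discoveries about a deposit's internal file schema
never touch analysis code.  Until such a deposit is inspected, the adapter accepts
the same per-subject CSV layout as the export (a documented stand-in
mapping) and reports any missing channels in the manifest instead of
failing, so incomplete subjects degrade gracefully downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .metrics import CohortMetrics, EISMagnitudes, MetricSeries, SubjectMetrics
from .protocol import ProtocolStep, ProtocolTimeline
from .synth import EITFrames, EISSpectra, SubjectRecording

EXPECTED_CHANNELS = ("ecg", "map", "pleth", "eit/thx", "eit/ab",
                     "eis/thx", "eis/ab", "eis/arm", "lbnp")


@dataclass
class CohortManifest:
    """Per-subject channel inventory of a loaded cohort."""

    entries: pd.DataFrame  # columns: subject, stop_level_mmhg, channel, present

    @property
    def subjects(self) -> list[str]:
        return sorted(self.entries["subject"].unique())

    def missing(self) -> pd.DataFrame:
        return self.entries[~self.entries["present"]]

    def complete_subjects(self) -> list[str]:
        ok = self.entries.groupby("subject")["present"].all()
        return sorted(ok[ok].index)


# ---------------------------------------------------------------------------
# native HDF5 container


def _write_protocol(grp: h5py.Group, protocol: ProtocolTimeline) -> None:
    pg = grp.create_group("protocol")
    pg.create_dataset("levels", data=[s.level for s in protocol.steps])
    pg.create_dataset("start_times", data=[s.start_time for s in protocol.steps])
    pg.create_dataset("end_times", data=[s.end_time for s in protocol.steps])
    pg.attrs["transition_duration"] = protocol.transition_duration
    pg.attrs["baseline_duration"] = protocol.baseline_duration


def _read_protocol(grp: h5py.Group) -> ProtocolTimeline:
    pg = grp["protocol"]
    steps = tuple(
        ProtocolStep(level=int(lv), start_time=float(t0), end_time=float(t1))
        for lv, t0, t1 in zip(pg["levels"][:], pg["start_times"][:], pg["end_times"][:])
    )
    return ProtocolTimeline(steps=steps,
                            transition_duration=float(pg.attrs["transition_duration"]),
                            baseline_duration=float(pg.attrs["baseline_duration"]))


def write_cohort(recordings: list[SubjectRecording], path) -> None:
    """Write a cohort to the native HDF5 container (overwrites)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "lbnpdet-cohort-v1"
        for rec in recordings:
            g = f.create_group(rec.subject_id)
            g.attrs["meta"] = json.dumps(rec.meta)
            _write_protocol(g, rec.protocol)
            g.create_dataset("ecg/rpeaks", data=rec.rpeak_times)
            g.create_dataset("map/time", data=rec.map_series[0])
            g.create_dataset("map/value", data=rec.map_series[1])
            g.create_dataset("pleth/time", data=rec.pleth_waveform[0])
            g.create_dataset("pleth/value", data=rec.pleth_waveform[1])
            for site, fr in rec.eit_frames.items():
                sg = g.create_group(f"eit/{site}")
                sg.create_dataset("time", data=fr.times)
                sg.create_dataset("values", data=fr.values)
                sg.create_dataset("channel_valid", data=fr.channel_valid)
            for site, sp in rec.eis_spectra.items():
                sg = g.create_group(f"eis/{site}")
                sg.create_dataset("time", data=sp.times)
                sg.create_dataset("freqs", data=sp.freqs)
                sg.create_dataset("z_real", data=sp.z.real)
                sg.create_dataset("z_imag", data=sp.z.imag)
            g.create_dataset("lbnp/time", data=rec.lbnp_series[0])
            g.create_dataset("lbnp/level", data=rec.lbnp_series[1])


def _read_native_subject(g: h5py.Group, subject_id: str) -> SubjectRecording:
    eit = {}
    if "eit" in g:
        for site in g["eit"]:
            sg = g[f"eit/{site}"]
            eit[site] = EITFrames(times=sg["time"][:], values=sg["values"][:],
                                  channel_valid=sg["channel_valid"][:].astype(bool))
    eis = {}
    if "eis" in g:
        for site in g["eis"]:
            sg = g[f"eis/{site}"]
            eis[site] = EISSpectra(times=sg["time"][:], freqs=sg["freqs"][:],
                                   z=sg["z_real"][:] + 1j * sg["z_imag"][:])
    return SubjectRecording(
        subject_id=subject_id,
        protocol=_read_protocol(g),
        rpeak_times=g["ecg/rpeaks"][:],
        map_series=(g["map/time"][:], g["map/value"][:]),
        pleth_waveform=(g["pleth/time"][:], g["pleth/value"][:]),
        eit_frames=eit,
        eis_spectra=eis,
        lbnp_series=(g["lbnp/time"][:], g["lbnp/level"][:]),
        meta=json.loads(g.attrs.get("meta", "{}")),
    )


def _manifest_for(recordings: list[SubjectRecording]) -> CohortManifest:
    rows = []
    for rec in recordings:
        present = {
            "ecg": rec.rpeak_times.size > 0,
            "map": rec.map_series[0].size > 0,
            "pleth": rec.pleth_waveform[0].size > 0,
            "lbnp": rec.lbnp_series[0].size > 0,
            "eit/thx": "thx" in rec.eit_frames,
            "eit/ab": "ab" in rec.eit_frames,
            "eis/thx": "thx" in rec.eis_spectra,
            "eis/ab": "ab" in rec.eis_spectra,
            "eis/arm": "arm" in rec.eis_spectra,
        }
        for ch in EXPECTED_CHANNELS:
            rows.append({"subject": rec.subject_id,
                         "stop_level_mmhg": rec.protocol.stop_level,
                         "channel": ch, "present": bool(present[ch])})
    return CohortManifest(entries=pd.DataFrame(rows))


def read_cohort(path, dialect: str = "native"
                ) -> tuple[list[SubjectRecording], CohortManifest]:
    """Load a cohort and report its channel inventory.

    ``native`` reads the HDF5 container; ``csvdir`` and ``zenodo`` read a
    directory of per-subject channel CSVs (see module docstring for the
    zenodo adapter's status).
    """
    if dialect == "native":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        recs = []
        with h5py.File(path, "r") as f:
            for subject_id in sorted(f.keys()):
                try:
                    recs.append(_read_native_subject(f[subject_id], subject_id))
                except KeyError as e:
                    raise InvalidInputError(
                        f"malformed container {path}: subject {subject_id} "
                        f"missing field {e}") from e
        return recs, _manifest_for(recs)
    if dialect in ("csvdir", "zenodo"):
        return _read_csv_dir(Path(path))
    raise InvalidInputError(f"unknown dialect {dialect!r}; use native|csvdir|zenodo")


# ---------------------------------------------------------------------------
# flat CSV export / import (one file per channel)


def export_cohort_csv(recordings: list[SubjectRecording], out_dir) -> None:
    out = Path(out_dir)
    for rec in recordings:
        d = out / rec.subject_id
        d.mkdir(parents=True, exist_ok=True)
        prot = pd.DataFrame({"level_mmhg": [s.level for s in rec.protocol.steps],
                             "start_s": [s.start_time for s in rec.protocol.steps],
                             "end_s": [s.end_time for s in rec.protocol.steps]})
        prot.to_csv(d / "protocol.csv", index=False)
        (d / "meta.json").write_text(json.dumps(
            {**rec.meta, "transition_duration": rec.protocol.transition_duration,
             "baseline_duration": rec.protocol.baseline_duration}))
        pd.DataFrame({"rpeak_s": rec.rpeak_times}).to_csv(d / "ecg_rpeaks.csv", index=False)
        pd.DataFrame({"time_s": rec.map_series[0], "map_mmhg": rec.map_series[1]}
                     ).to_csv(d / "map.csv", index=False)
        pd.DataFrame({"time_s": rec.pleth_waveform[0], "pleth_au": rec.pleth_waveform[1]}
                     ).to_csv(d / "pleth.csv", index=False)
        pd.DataFrame({"time_s": rec.lbnp_series[0], "lbnp_mmhg": rec.lbnp_series[1]}
                     ).to_csv(d / "lbnp.csv", index=False)
        for site, fr in rec.eit_frames.items():
            df = pd.DataFrame(fr.values,
                              columns=[f"ch{c:03d}_ohm" for c in range(fr.values.shape[1])])
            df.insert(0, "time_s", fr.times)
            df.to_csv(d / f"eit_{site}.csv", index=False)
            pd.DataFrame({"channel_valid": fr.channel_valid.astype(int)}
                         ).to_csv(d / f"eit_{site}_valid.csv", index=False)
        for site, sp in rec.eis_spectra.items():
            cols = {"time_s": sp.times}
            for j, f in enumerate(sp.freqs):
                cols[f"re_{f:.10g}Hz_ohm"] = sp.z.real[:, j]
                cols[f"im_{f:.10g}Hz_ohm"] = sp.z.imag[:, j]
            pd.DataFrame(cols).to_csv(d / f"eis_{site}.csv", index=False)


def _read_csv_dir(root: Path) -> tuple[list[SubjectRecording], CohortManifest]:
    if not root.is_dir():
        raise FileNotFoundError(root)
    recs = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        try:
            prot_df = pd.read_csv(d / "protocol.csv")
            meta = json.loads((d / "meta.json").read_text()) if (d / "meta.json").exists() else {}
            steps = tuple(ProtocolStep(int(r.level_mmhg), float(r.start_s), float(r.end_s))
                          for r in prot_df.itertuples())
            protocol = ProtocolTimeline(
                steps=steps,
                transition_duration=float(meta.get("transition_duration", 48.0)),
                baseline_duration=float(meta.get("baseline_duration", 300.0)))
        except (FileNotFoundError, KeyError, ValueError) as e:
            raise InvalidInputError(f"malformed subject directory {d}: {e}") from e
        eit = {}
        for site in ("thx", "ab"):
            f = d / f"eit_{site}.csv"
            if not f.exists():
                continue
            df = pd.read_csv(f)
            valid_f = d / f"eit_{site}_valid.csv"
            nch = df.shape[1] - 1
            valid = (pd.read_csv(valid_f)["channel_valid"].to_numpy(bool)
                     if valid_f.exists() else np.ones(nch, dtype=bool))
            eit[site] = EITFrames(times=df["time_s"].to_numpy(),
                                  values=df.drop(columns="time_s").to_numpy(),
                                  channel_valid=valid)
        eis = {}
        for site in ("thx", "ab", "arm"):
            f = d / f"eis_{site}.csv"
            if not f.exists():
                continue
            df = pd.read_csv(f)
            re_cols = [c for c in df.columns if c.startswith("re_")]
            im_cols = [c for c in df.columns if c.startswith("im_")]
            freqs = np.array([float(c.split("_")[1][:-2]) for c in re_cols])
            eis[site] = EISSpectra(times=df["time_s"].to_numpy(), freqs=freqs,
                                   z=df[re_cols].to_numpy() + 1j * df[im_cols].to_numpy())

        def _col(fname, col):
            f = d / fname
            return pd.read_csv(f)[col].to_numpy() if f.exists() else np.array([])

        recs.append(SubjectRecording(
            subject_id=d.name, protocol=protocol,
            rpeak_times=_col("ecg_rpeaks.csv", "rpeak_s"),
            map_series=(_col("map.csv", "time_s"), _col("map.csv", "map_mmhg")),
            pleth_waveform=(_col("pleth.csv", "time_s"), _col("pleth.csv", "pleth_au")),
            eit_frames=eit, eis_spectra=eis,
            lbnp_series=(_col("lbnp.csv", "time_s"), _col("lbnp.csv", "lbnp_mmhg")),
            meta=meta))
    if not recs:
        raise InvalidInputError(f"no subject directories found under {root}")
    return recs, _manifest_for(recs)


# ---------------------------------------------------------------------------
# tidy metric exchange (extract -> analyze/ml)


def save_metrics(cohort: CohortMetrics, out_dir) -> None:
    """Write extracted metrics as tidy CSVs (level table, series, EIS, HRV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.level_table().to_csv(out / "level_table.csv", index=False)
    prot_rows, series_rows, eis_rows, hrv_frames = [], [], [], []
    for sm in cohort.subjects:
        for s in sm.protocol.steps:
            prot_rows.append({"subject": sm.subject_id, "level_mmhg": s.level,
                              "start_s": s.start_time, "end_s": s.end_time,
                              "transition_s": sm.protocol.transition_duration})
        for name, series in sm.series.items():
            series_rows.append(pd.DataFrame({
                "subject": sm.subject_id, "metric": name,
                "time_s": series.times, "value": series.values,
                "sd": series.sd if series.sd is not None else np.nan}))
        for site, mags in sm.eis.items():
            n, k = mags.mag.shape
            eis_rows.append(pd.DataFrame({
                "subject": sm.subject_id, "site": site,
                "time_s": np.repeat(mags.times, k),
                "frequency_hz": np.tile(mags.freqs, n),
                "magnitude_ohm": mags.mag.ravel()}))
        h = sm.hrv.reset_index()
        h.insert(0, "subject", sm.subject_id)
        hrv_frames.append(h)
    pd.DataFrame(prot_rows).to_csv(out / "protocol.csv", index=False)
    pd.concat(series_rows, ignore_index=True).to_csv(out / "series.csv", index=False)
    pd.concat(eis_rows, ignore_index=True).to_csv(out / "eis_magnitude.csv", index=False)
    pd.concat(hrv_frames, ignore_index=True).to_csv(out / "hrv.csv", index=False)
    (out / "extract_meta.json").write_text(json.dumps(
        {"transition_skip": cohort.transition_skip}))


def load_metrics(in_dir) -> CohortMetrics:
    """Reconstruct a :class:`CohortMetrics` from :func:`save_metrics` output."""
    root = Path(in_dir)
    if not (root / "series.csv").exists():
        raise InvalidInputError(
            f"{root} does not look like an extracted-metrics directory "
            "(missing series.csv); run the extract stage first")
    prot = pd.read_csv(root / "protocol.csv")
    series = pd.read_csv(root / "series.csv")
    eis = pd.read_csv(root / "eis_magnitude.csv")
    hrv = pd.read_csv(root / "hrv.csv")
    meta = json.loads((root / "extract_meta.json").read_text()) \
        if (root / "extract_meta.json").exists() else {}
    subjects = []
    for subject in sorted(prot["subject"].unique()):
        p = prot[prot["subject"] == subject].sort_values("start_s")
        protocol = ProtocolTimeline(
            steps=tuple(ProtocolStep(int(r.level_mmhg), float(r.start_s), float(r.end_s))
                        for r in p.itertuples()),
            transition_duration=float(p["transition_s"].iloc[0]))
        sdict = {}
        for name, grp in series[series["subject"] == subject].groupby("metric"):
            grp = grp.sort_values("time_s")
            sd = grp["sd"].to_numpy()
            sdict[name] = MetricSeries(
                metric_name=name, times=grp["time_s"].to_numpy(),
                values=grp["value"].to_numpy(),
                sd=None if np.all(np.isnan(sd)) else sd)
        edict = {}
        for site, grp in eis[eis["subject"] == subject].groupby("site"):
            piv = grp.pivot_table(index="time_s", columns="frequency_hz",
                                  values="magnitude_ohm").sort_index()
            edict[site] = EISMagnitudes(site=site, times=piv.index.to_numpy(),
                                        freqs=piv.columns.to_numpy(float),
                                        mag=piv.to_numpy())
        h = hrv[hrv["subject"] == subject].drop(columns="subject").set_index("time_s")
        subjects.append(SubjectMetrics(subject_id=subject, protocol=protocol,
                                       series=sdict, eis=edict, hrv=h))
    return CohortMetrics(subjects=subjects,
                         transition_skip=meta.get("transition_skip"))
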