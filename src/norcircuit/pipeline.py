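"""End-to-end cohort analysis: preprocess -> behavior -> epochs ->
connectivity -> (maps) -> statistics, from a data directory or from
in-memory sessions, emitting a per-animal cohort table and a table of
statistical results.

Inference mirrors the study design: per-test alpha = 0.05 with no
multiplicity correction by default (a Holm option is available),
Student's equal-variance t for group contrasts, one-sample t against 0
for directional lead-lag means, and Pearson brain-behavior
correlations screened for a single gross outlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DEFAULT_BANDS, PAIRS, Recording, TrackingTrace
from . import behavior as beh
from . import connectivity as conn
from . import io as ncio
from . import spatialmap
from .preprocess import PreprocConfig, preprocess
from .stats import (ALPHA, StatResult, holm_correction, one_sample_ttest,
                    pearson_outlier, two_sample_ttest)

log = logging.getLogger("norcircuit")

#: behavioral columns contrasted between groups
BEHAVIOR_MEASURES = ("di", "pct_novel", "time_novel", "time_familiar",
                     "total_distance")


@dataclass
class PipelineConfig:
    """All knobs of a cohort run; every field has a recorded default."""

    data_dir: str = ""
    out_dir: str = ""
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    pairs: tuple = PAIRS
    seg_len_s: float = 1.0
    overlap: float = 0.5
    pre: float = 2.0
    post: float = 1.0
    event_label: str = "novel"
    pool: str = "animal"
    max_lag_ms: float | None = None
    absolute_peak: bool = False
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    make_maps: bool = False
    map_bin_size: float = 5.0
    map_win_s: float = 1.0
    map_min_occ: int = 3
    equal_var: bool = True
    holm: bool = False
    alpha: float = ALPHA

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config file with sections data/bands/welch/xcorr/stats/map."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        data = raw.get("data", {})
        cfg.data_dir = data.get("dir", cfg.data_dir)
        cfg.out_dir = data.get("out", cfg.out_dir)
        cfg.event_label = data.get("event_label", cfg.event_label)
        if "bands" in raw:
            cfg.bands = {k: (float(v[0]), float(v[1]))
                         for k, v in raw["bands"].items()}
        welch = raw.get("welch", {})
        cfg.seg_len_s = float(welch.get("seg_len_s", cfg.seg_len_s))
        cfg.overlap = float(welch.get("overlap", cfg.overlap))
        cfg.pool = welch.get("pool", cfg.pool)
        xcorr = raw.get("xcorr", {})
        if "max_lag_ms" in xcorr:
            cfg.max_lag_ms = float(xcorr["max_lag_ms"])
        cfg.absolute_peak = bool(xcorr.get("absolute_peak", cfg.absolute_peak))
        stats_sec = raw.get("stats", {})
        cfg.equal_var = bool(stats_sec.get("equal_var", cfg.equal_var))
        cfg.holm = bool(stats_sec.get("holm", cfg.holm))
        cfg.alpha = float(stats_sec.get("alpha", cfg.alpha))
        pp = raw.get("preproc", {})
        cfg.preproc = PreprocConfig(
            line_freq=float(pp.get("line_freq", 50.0)),
            lowpass_hz=float(pp.get("lowpass_hz", 250.0)),
            artifact_z=float(pp.get("artifact_z", 6.0)),
        )
        mp = raw.get("map", {})
        cfg.make_maps = bool(mp.get("enabled", cfg.make_maps))
        cfg.map_bin_size = float(mp.get("bin_size", cfg.map_bin_size))
        cfg.map_win_s = float(mp.get("win_s", cfg.map_win_s))
        cfg.map_min_occ = int(mp.get("min_occ", cfg.map_min_occ))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        d["pairs"] = [list(p) for p in self.pairs]
        return d


def _conn_col(kind: str, pair_key: str, band: str) -> str:
    return f"{kind}_{pair_key}_{band}"


def analyze_session(rec: Recording, trace: TrackingTrace,
                    cfg: PipelineConfig) -> dict:
    """Run one animal's session through the full single-animal chain.

    Returns a flat row for the cohort table. Animals without any valid
    epoch carry NaN connectivity (flagged missing, never zero-filled).
    """
    pp = preprocess(rec, cfg.preproc)
    bouts = beh.detect_object_bouts(trace)
    summary = beh.behavior_summary(trace, bouts)
    onsets = beh.novel_event_onsets(bouts, label=cfg.event_label)
    epochs, dropped = conn.extract_epochs(pp, onsets, cfg.pre, cfg.post)
    row = {"animal_id": rec.animal_id, "group": rec.group_label}
    row.update(summary.to_dict())
    row["n_epochs"] = len(epochs)
    row["n_epochs_dropped"] = len(dropped)
    if dropped:
        log.info("%s: dropped %d epoch(s): %s", rec.animal_id, len(dropped),
                 "; ".join(f"t={t:.2f}s ({why})" for t, why in dropped))
    if epochs:
        ac = conn.animal_connectivity(
            epochs, cfg.bands, cfg.pairs, cfg.seg_len_s, cfg.overlap,
            pool=cfg.pool, max_lag_ms=cfg.max_lag_ms,
            absolute_peak=cfg.absolute_peak)
        for a, b in cfg.pairs:
            key = f"{a}-{b}"
            for bn in cfg.bands:
                row[_conn_col("coh", key, bn)] = ac.coherence[key][bn]
                row[_conn_col("rmax", key, bn)] = ac.r_max[key][bn]
                row[_conn_col("lag", key, bn)] = ac.lag_ms[key][bn]
    else:
        log.warning("%s: no valid epochs; connectivity flagged missing",
                    rec.animal_id)
        for a, b in cfg.pairs:
            key = f"{a}-{b}"
            for bn in cfg.bands:
                for kind in ("coh", "rmax", "lag"):
                    row[_conn_col(kind, key, bn)] = np.nan
    return row


def analyze_cohort(sessions, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Build the cohort table from (rec, trace) session pairs."""
    cfg = cfg or PipelineConfig()
    rows = [analyze_session(rec, trace, cfg) for rec, trace in sessions]
    return pd.DataFrame(rows)


def _valid(series: pd.Series) -> np.ndarray:
    return series.dropna().to_numpy(dtype=float)


def cohort_stats(table: pd.DataFrame, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """All statistical results for a cohort table.

    Group contrasts (t-test) on the behavioral measures and every
    pair x band connectivity measure; one-sample t of each group's
    lead-lag means against 0; Pearson DI-vs-connectivity per group with
    the outlier screen.
    """
    cfg = cfg or PipelineConfig()
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) < 2:
        raise ValueError("cohort stats need at least 2 groups")
    g0, g1 = groups[:2]
    t0 = table[table["group"] == g0]
    t1 = table[table["group"] == g1]

    conn_cols = [
        _conn_col(kind, f"{a}-{b}", bn)
        for kind in ("coh", "rmax", "lag")
        for a, b in cfg.pairs for bn in cfg.bands
    ]
    results = []

    def add(kind, measure, group, res: StatResult):
        d = res.to_dict()
        d.update({"analysis": kind, "measure": measure, "group": group})
        results.append(d)

    for col in list(BEHAVIOR_MEASURES) + conn_cols:
        a, b = _valid(t0[col]), _valid(t1[col])
        if len(a) >= 2 and len(b) >= 2:
            add("group_contrast", col, f"{g0} vs {g1}",
                two_sample_ttest(a, b, names=(g0, g1),
                                 equal_var=cfg.equal_var))
    for gname, tg in ((g0, t0), (g1, t1)):
        for a, b in cfg.pairs:
            for bn in cfg.bands:
                col = _conn_col("lag", f"{a}-{b}", bn)
                vals = _valid(tg[col])
                if len(vals) >= 2:
                    add("lag_vs_zero", col, gname,
                        one_sample_ttest(vals, 0.0, name=col))
    for gname, tg in ((g0, t0), (g1, t1)):
        sub = tg.dropna(subset=["di"])
        for col in conn_cols:
            ok = sub.dropna(subset=[col])
            if len(ok) < 4:
                continue
            try:
                add("di_correlation", col, gname,
                    pearson_outlier(ok["di"].to_numpy(float),
                                    ok[col].to_numpy(float),
                                    ids=list(ok["animal_id"]),
                                    alpha=cfg.alpha))
            except ValueError as exc:  # degenerate (constant) inputs
                log.warning("skipping DI correlation %s (%s): %s",
                            col, gname, exc)
    df = pd.DataFrame(results)
    df["significant"] = df["p_value"] < cfg.alpha
    if cfg.holm:
        df["p_holm"] = holm_correction(df["p_value"].to_numpy())
    return df


def load_cohort_dir(data_dir, cfg: PipelineConfig | None = None) -> list:
    """Load a generated (or equivalently organized) cohort directory.

    Expects groups.tsv naming each animal's LFP and tracking file, and
    manifest.json for arena/object geometry. Missing or unreadable
    animals are skipped with a warning (partial cohorts allowed).
    """
    data_dir = Path(data_dir)
    groups = pd.read_csv(data_dir / "groups.tsv", sep="\t")
    manifest = ncio.read_json(data_dir / "manifest.json")
    objects = ncio.objects_from_config(manifest.get("objects", []))
    arena = manifest.get("params", {})
    first = next(iter(arena.values()), {}) if isinstance(arena, dict) else {}
    arena_wh = tuple(first.get("arena", (75.0, 75.0)))
    sessions, failures = [], []
    for _, row in groups.iterrows():
        try:
            rec = ncio.read_recording(data_dir / row["lfp"],
                                      animal_id=row["animal_id"],
                                      group_label=row["group"])
            trace = ncio.read_tracking(data_dir / row["tracking"],
                                       arena=arena_wh, objects=objects)
            sessions.append((rec, trace))
        except (OSError, ValueError) as exc:
            failures.append(f"{row['animal_id']}: {exc}")
    if failures:
        log.warning("skipped %d animal(s):\n  %s", len(failures),
                    "\n  ".join(failures))
    if not sessions:
        raise FileNotFoundError(
            "no readable animal in cohort; failures: " + "; ".join(failures))
    return sessions


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full cohort analysis from ``cfg.data_dir``.

    Writes cohort.tsv (one row per animal), stats.tsv, params.json
    (the exact configuration applied) and optional spatial maps under
    ``cfg.out_dir``. Deterministic: identical inputs and config give
    byte-identical report files. Returns the tables and output paths.
    """
    out_dir = Path(cfg.out_dir or (Path(cfg.data_dir) / "report"))
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = load_cohort_dir(cfg.data_dir, cfg)
    table = analyze_cohort(sessions, cfg)
    stats = cohort_stats(table, cfg)
    table.to_csv(out_dir / "cohort.tsv", sep="\t", index=False,
                 float_format="%.6f")
    stats.to_csv(out_dir / "stats.tsv", sep="\t", index=False,
                 float_format="%.6g")
    sidecar = cfg.to_dict()
    sidecar.pop("data_dir", None)   # paths are not analysis parameters
    sidecar.pop("out_dir", None)
    sidecar["preproc"] = cfg.preproc.to_dict()
    sidecar["lag_sign_convention"] = "positive = first-named region leads"
    ncio.write_json(sidecar, out_dir / "params.json")
    maps = {}
    if cfg.make_maps:
        manifest = ncio.read_json(Path(cfg.data_dir) / "manifest.json")
        objects = ncio.objects_from_config(manifest.get("objects", []))
        for (rec, trace) in sessions:
            pp = preprocess(rec, cfg.preproc)
            for a, b in cfg.pairs:
                for bn, band in cfg.bands.items():
                    smap = spatialmap.coherence_map(
                        pp, trace, (a, b), band, cfg.map_bin_size,
                        cfg.map_win_s, cfg.map_min_occ)
                    stem = f"map_{rec.animal_id}_{a}-{b}_{bn}"
                    spatialmap.write_map(smap, out_dir / f"{stem}.tsv",
                                         out_dir / f"{stem}_occ.tsv")
                    maps[stem] = smap
    return {"cohort": table, "stats": stats, "out_dir": out_dir, "maps": maps}
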