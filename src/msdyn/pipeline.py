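"""End-to-end study driver: simulate -> preprocess -> segment -> stats.

`analyze_study` runs the whole chain in memory on a simulated (or loaded)
cohort; `run_pipeline` wraps it with a resolved on-disk layout (qc/,
templates/, states/, params/, stats/, log.txt) so every output is
re-derivable from inputs + config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .clustering import canonical_labels, group_templates, taahc
from .containers import QCReport, Recording, TemplateSet
from .segmentation import extract_peak_maps, find_gfp_peaks, gfp, segment
from .stats import compare_parameters, compare_transitions, correlate_with_scores
from .synthetic import StudyBundle, make_group_study

log = logging.getLogger("msdyn")

__all__ = ["PipelineConfig", "fit_subject_templates", "analyze_study", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable settings, defaulting to the reference analysis choices."""

    band: tuple[float, float] = (0.5, 80.0)
    notch: float | None = 50.0
    epoch_s: float = 2.0
    amp_uv: float = 80.0
    min_retained_s: float = 180.0  # inclusion floor; lower it for short demos
    max_bad_channels: int = 10
    ms_band: tuple[float, float] = (2.0, 20.0)
    k: int = 4
    smooth_ms: float = 30.0
    besag: float = 10.0
    min_duration_ms: float = 30.0
    min_separation_ms: float = 10.0
    max_peak_maps: int | None = None  # None: cluster every GFP-peak map
    alpha: float = 0.05
    t_variant: str = "auto"
    # simulation block (used when inputs == "simulate")
    n_per_group: tuple[int, int] = (23, 18)
    sim_srate: float = 250.0
    sim_duration_s: float = 300.0
    sim_snr: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("invalid broadband edges")
        if not (0 < self.ms_band[0] < self.ms_band[1] < self.band[1]):
            raise ValueError("invalid microstate band")
        if self.k < 2 or self.k > 7:
            raise ValueError("k must be in 2..7")
        if min(self.n_per_group) < 2:
            raise ValueError("need >= 2 subjects per group")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("band", "ms_band", "n_per_group"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("band", "ms_band", "n_per_group"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _thin(idx: np.ndarray, max_n: int | None) -> np.ndarray:
    """Deterministic even thinning of peak indices to at most max_n."""
    if max_n is None or idx.size <= max_n:
        return idx
    pick = np.linspace(0, idx.size - 1, max_n).round().astype(int)
    return idx[np.unique(pick)]


def fit_subject_templates(rec: Recording, cfg: PipelineConfig) -> TemplateSet:
    """GFP peaks -> peak maps -> T-AAHC at the configured k."""
    g = gfp(rec)
    peaks = find_gfp_peaks(g, cfg.min_separation_ms)
    peaks = _thin(peaks, cfg.max_peak_maps)
    maps, weights = extract_peak_maps(rec, peaks)
    ts = taahc(maps, cfg.k, weights=weights)
    ts.ch_names = list(rec.ch_names)
    return ts


@dataclass
class SubjectResult:
    subject_id: str
    qc: QCReport
    templates: TemplateSet
    params: pd.DataFrame
    transitions: pd.DataFrame


@dataclass
class StudyResult:
    params: pd.DataFrame  # tidy: subject_id, state, duration_ms, ...
    transitions: pd.DataFrame  # subject_id, from, to, probability
    group_templates: dict[str, TemplateSet]
    subject_templates: dict[str, TemplateSet]
    qc: dict[str, QCReport]
    stats_params: pd.DataFrame
    stats_transitions: pd.DataFrame
    correlations: pd.DataFrame
    quarantined: dict[str, str] = field(default_factory=dict)


def analyze_study(bundle: StudyBundle, cfg: PipelineConfig) -> StudyResult:
    """Full in-memory analysis of a cohort.

    Per subject: clean, extract GFP-peak maps, T-AAHC. Per group: second-
    level T-AAHC over subject templates, canonically labeled A-D. Each
    subject is then backfit with their group's templates and the temporal
    parameters feed the two-group statistics.
    """
    cfg.validate()
    design = bundle.design
    cleaned: dict[str, Recording] = {}
    qc: dict[str, QCReport] = {}
    subject_ts: dict[str, TemplateSet] = {}
    quarantined: dict[str, str] = {}

    for sid, rec in zip(design["subject_id"], bundle.recordings):
        try:
            if rec is None:
                raise ValueError("no recording available")
            r, q = pp.clean(
                rec, band=cfg.band, notch=cfg.notch, epoch_s=cfg.epoch_s,
                amp_uv=cfg.amp_uv, max_bad_channels=cfg.max_bad_channels,
                ms_band=cfg.ms_band,
            )
            q.min_retained_s = cfg.min_retained_s
            if not q.passes_inclusion:
                raise ValueError(
                    f"only {q.retained_seconds:.0f} s retained "
                    f"(< {cfg.min_retained_s:.0f} s inclusion floor)"
                )
            cleaned[sid] = r
            qc[sid] = q
            subject_ts[sid] = fit_subject_templates(r, cfg)
        except Exception as exc:  # quarantine, keep going
            quarantined[sid] = f"{type(exc).__name__}: {exc}"
            log.warning("subject %s quarantined: %s", sid, exc)

    ok = design[design["subject_id"].isin(cleaned)]
    if ok.empty:
        raise RuntimeError("empty cohort: every subject failed preprocessing")

    gts: dict[str, TemplateSet] = {}
    for group, sub in ok.groupby("group", sort=False):
        sets = [subject_ts[s] for s in sub["subject_id"]]
        gt = group_templates(sets, k=cfg.k)
        gts[group] = canonical_labels(gt) if cfg.k == 4 else gt

    prows, trows = [], []
    for _, row in ok.iterrows():
        sid, group = row["subject_id"], row["group"]
        ts = gts[group]
        _, par = segment(
            cleaned[sid], ts, smooth_ms=cfg.smooth_ms, besag=cfg.besag,
            min_duration_ms=cfg.min_duration_ms,
        )
        pf = par.to_frame()
        pf.insert(0, "subject_id", sid)
        prows.append(pf)
        tf = par.transition_frame()
        tf.insert(0, "subject_id", sid)
        trows.append(tf)

    params = pd.concat(prows, ignore_index=True)
    transitions = pd.concat(trows, ignore_index=True)

    stats_params = compare_parameters(params, design, variant=cfg.t_variant)
    stats_transitions = compare_transitions(transitions, design,
                                            variant=cfg.t_variant)
    tp = transitions.assign(cell=transitions["from"] + "_to_" + transitions["to"])
    wide = tp.pivot(index="subject_id", columns="cell",
                    values="probability").reset_index()
    feats = params.pivot(index="subject_id", columns="state",
                         values="duration_ms").add_prefix("duration_")
    feats = feats.reset_index().merge(wide, on="subject_id")
    corr = correlate_with_scores(
        feats, design, [c for c in feats.columns if c != "subject_id"]
    )
    return StudyResult(
        params=params,
        transitions=transitions,
        group_templates=gts,
        subject_templates=subject_ts,
        qc=qc,
        stats_params=stats_params,
        stats_transitions=stats_transitions,
        correlations=corr,
        quarantined=quarantined,
    )


def run_pipeline(cfg: PipelineConfig, inputs: str = "simulate",
                 out_dir: str | Path = "msdyn-run") -> Path:
    """Run the chain end to end and write a deterministic directory layout.

    ``inputs="simulate"`` builds the cohort from the config's simulation
    block; otherwise ``inputs`` is a directory of per-subject ``.npz``
    recordings plus a ``design.tsv`` (written by
    :func:`msdyn.io.save_study`).
    """
    cfg.validate()
    out = Path(out_dir)
    for sub in ("qc", "templates", "states", "params", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt")
    log.addHandler(handler)
    try:
        cfg.to_yaml(out / "config.yaml")
        if inputs == "simulate":
            bundle = make_group_study(
                n_per_group=cfg.n_per_group, seed=cfg.seed,
                srate=cfg.sim_srate, duration_s=cfg.sim_duration_s,
                snr=cfg.sim_snr,
            )
        else:
            from .io import load_study

            bundle = load_study(inputs)
        res = analyze_study(bundle, cfg)

        bundle.design.to_csv(out / "design.tsv", sep="\t", index=False)
        for sid, q in res.qc.items():
            (out / "qc" / f"{sid}.json").write_text(json.dumps(q.to_dict()))
        for group, ts in res.group_templates.items():
            df = pd.DataFrame(ts.maps.T, columns=ts.labels)
            df.insert(0, "channel", ts.ch_names)
            df.to_csv(out / "templates" / f"group-{group}.tsv", sep="\t",
                      index=False)
        res.params.to_csv(out / "params" / "params.tsv", sep="\t", index=False)
        res.transitions.to_csv(out / "params" / "transitions.tsv", sep="\t",
                               index=False)
        res.stats_params.to_csv(out / "stats" / "parameters.tsv", sep="\t",
                                index=False)
        res.stats_transitions.to_csv(out / "stats" / "transitions.tsv",
                                     sep="\t", index=False)
        res.correlations.to_csv(out / "stats" / "correlations.tsv", sep="\t",
                                index=False)
        if res.quarantined:
            (out / "quarantined.json").write_text(json.dumps(res.quarantined))
        return out
    except Exception:
        log.error("pipeline failed:\n%s", traceback.format_exc())
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
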