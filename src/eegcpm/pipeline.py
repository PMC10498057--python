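"""End-to-end orchestration: simulate/load -> preprocess -> arousal ->
connectomes -> group statistics -> CPM, from a single config.

Every intermediate artifact is written to the run directory (arousal table,
exclusion report, connectome matrices, statistics, CPM tables) together
with a JSON manifest of the resolved configuration, so each stage is
independently checkable and a rerun with the same config and seed
reproduces all outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .connectivity import connectome_per_band
from .core import DEFAULT_BANDS, BandDefinition, Recording
from .cpm import cpm_loocv, permutation_test, vectorize_connectomes
from .preprocess import flag_exclusions, preprocess_recording
from .simulate import CouplingEdge, SyntheticSpec, gen_cohort
from .spectral import alpha_power_db, median_split, welch_psd
from .stats import GroupSummary, anova_from_summary, bonferroni_posthoc, summarize, ttest_from_summary

log = logging.getLogger("eegcpm")


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults equal the emulated study's stated values wherever one exists
    (2-s windows/epochs, 8-13 Hz arousal band, p < .05 edge threshold,
    1000 permutations, 100 uV / half-time exclusion rule).
    """

    out_dir: str = "eegcpm_run"
    input_dir: str | None = None  # read recordings from here instead of simulating
    behavior_file: str | None = None
    simulate: dict = field(default_factory=dict)  # SyntheticSpec overrides
    bands: list[tuple[str, float, float]] = field(
        default_factory=lambda: [(b.name, b.lo, b.hi) for b in DEFAULT_BANDS]
    )
    window: float = 2.0
    epoch_length: float = 2.0
    arousal_band: tuple[float, float] = (8.0, 13.0)
    amp_thresh: float = 100.0
    time_frac: float = 0.5
    cpm_bands: list[str] = field(default_factory=lambda: ["alpha"])
    cpm_group: str = "M"  # sex label of the modeled subgroup, or "all"
    threshold: float = 0.05
    n_perm: int = 1000
    control_age: bool = False
    seed: int = 0
    write_recordings: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(str(n), float(lo), float(hi)) for n, lo, hi in self.bands)

    def synthetic_spec(self) -> SyntheticSpec:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        if "coupling_edges" in params:
            params["coupling_edges"] = tuple(
                CouplingEdge(**e) if isinstance(e, dict) else CouplingEdge(*e)
                for e in params["coupling_edges"]
            )
        if "bands" in params:
            params["bands"] = tuple(BandDefinition(*b) for b in params["bands"])
        else:
            params["bands"] = self.band_definitions()
        return SyntheticSpec(**params)


def _load_inputs(config: RunConfig) -> tuple[list[Recording], pd.DataFrame]:
    if config.input_dir is None:
        spec = config.synthetic_spec()
        log.info("simulating cohort: %d subjects, %d channels", spec.n_subjects, spec.n_channels)
        return gen_cohort(spec)
    in_dir = Path(config.input_dir)
    if config.behavior_file is None:
        raise PipelineError("load", "behavior_file is required when input_dir is given")
    if not Path(config.behavior_file).exists():
        raise PipelineError("load", f"behavior file not found: {config.behavior_file}")
    behavior = eio.read_behavior_table(config.behavior_file)
    recordings = []
    for sid in behavior["subject_id"]:
        candidates = [in_dir / f"{sid}.tsv", in_dir / f"{sid}.edf"]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise PipelineError("load", f"no recording for subject {sid} in {in_dir}")
        recordings.append(eio.read_recording(path, subject_id=sid))
    return recordings, behavior


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path) -> Path:
    recordings, behavior = _load_inputs(config)
    if config.write_recordings:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in recordings:
            eio.write_recording(rec, rec_dir / f"{rec.subject_id}.tsv")
    eio.write_behavior_table(behavior, out / "behavior.tsv")

    # --- preprocess + exclusion screening ---
    try:
        processed, reports = [], []
        for rec in recordings:
            clean = preprocess_recording(rec)
            report = flag_exclusions(clean, config.amp_thresh, config.time_frac)
            reports.append(report.to_frame(clean.channel_labels))
            if report.subject_excluded:
                log.warning("subject %s excluded by amplitude rule", rec.subject_id)
                continue
            processed.append(clean)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("preprocess", str(err)) from err
    pd.concat(reports, ignore_index=True).to_csv(out / "exclusions.tsv", sep="\t", index=False)
    if not processed:
        raise PipelineError("preprocess", "every subject was excluded")
    kept_ids = [r.subject_id for r in processed]
    behavior = behavior[behavior["subject_id"].isin(kept_ids)].reset_index(drop=True)

    # --- spectra + arousal index ---
    try:
        alpha_db = []
        spectra_dir = out / "spectra"
        spectra_dir.mkdir(exist_ok=True)
        for rec in processed:
            psd = welch_psd(rec, window=config.window)
            psd.to_frame().to_csv(spectra_dir / f"{rec.subject_id}.tsv", sep="\t", index=False)
            alpha_db.append(alpha_power_db(psd, band=tuple(config.arousal_band)))
    except Exception as err:  # noqa: BLE001
        raise PipelineError("spectral", str(err)) from err

    # the median split indexes arousal within the modeled subgroup (men)
    sex = behavior.set_index("subject_id").loc[kept_ids, "sex"]
    split_ids = [s for s in kept_ids if config.cpm_group in ("all", sex[s])]
    split_vals = [alpha_db[kept_ids.index(s)] for s in split_ids]
    try:
        arousal = median_split(split_vals, split_ids)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("spectral", str(err)) from err
    full = pd.DataFrame({"subject_id": kept_ids, "alpha_db": alpha_db})
    full = full.merge(arousal[["subject_id", "group"]], on="subject_id", how="left")
    full["group"] = full["group"].fillna("other")
    full.to_csv(out / "arousal.tsv", sep="\t", index=False)

    # --- connectomes ---
    bands = config.band_definitions()
    try:
        conn_dir = out / "connectomes"
        conn_dir.mkdir(exist_ok=True)
        connectomes: dict[str, list] = {b.name: [] for b in bands}
        for rec in processed:
            for conn in connectome_per_band(rec, bands, epoch_length=config.epoch_length):
                connectomes[conn.band.name].append(conn)
                eio.write_matrix(
                    conn.matrix, conn.channel_labels, conn_dir / f"{rec.subject_id}_{conn.band.name}.tsv"
                )
    except Exception as err:  # noqa: BLE001
        raise PipelineError("connectivity", str(err)) from err

    # --- group statistics ---
    stats_out = _group_statistics(full, behavior)
    with open(out / "group_stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2)

    # --- CPM ---
    cpm_rows = []
    rng = np.random.default_rng(config.seed)
    merged = behavior.merge(full, on="subject_id")
    model_mask = (
        np.ones(len(merged), dtype=bool)
        if config.cpm_group == "all"
        else (merged["sex"] == config.cpm_group).to_numpy()
    )
    y = merged.loc[model_mask, "rating"].to_numpy()
    ages = merged.loc[model_mask, "age"].to_numpy(dtype=float) if config.control_age else None
    model_ids = merged.loc[model_mask, "subject_id"].tolist()
    try:
        for band_name in config.cpm_bands:
            conns = [c for c in connectomes[band_name] if c.subject_id in model_ids]
            X = vectorize_connectomes(conns)
            run = cpm_loocv(X, y, threshold=config.threshold, covariate=ages)
            p_perm = permutation_test(
                X, y, run, n_perm=config.n_perm, seed=rng, covariate=ages
            )
            for net in ("combined", "positive", "negative"):
                res = run[net]
                cpm_rows.append(
                    {
                        "band": band_name,
                        "network": net,
                        "r": res.r,
                        "p": res.p,
                        "p_perm": p_perm[net],
                    }
                )
            pred = pd.DataFrame(
                {
                    "subject_id": model_ids,
                    "observed": y,
                    **{f"predicted_{net}": run[net].predicted for net in run.results},
                }
            )
            pred.to_csv(out / f"cpm_predictions_{band_name}.tsv", sep="\t", index=False)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("cpm", str(err)) from err
    pd.DataFrame(cpm_rows).to_csv(out / "cpm_results.tsv", sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "n_subjects_in": len(recordings),
        "n_subjects_kept": len(processed),
        "bands": [(b.name, b.lo, b.hi) for b in bands],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("run complete: %s", out)
    return out


def _group_statistics(arousal: pd.DataFrame, behavior: pd.DataFrame) -> dict:
    """Behavioral and alpha-power comparisons across the three cohorts
    (high-arousal members, low-arousal members of the modeled subgroup, and
    everyone else), when each group has at least two subjects."""
    merged = behavior.merge(arousal, on="subject_id")
    out: dict = {}
    groups: list[GroupSummary] = []
    alpha_groups: list[GroupSummary] = []
    for label in ("high", "low", "other"):
        sub = merged[merged["group"] == label]
        if len(sub) >= 2:
            groups.append(summarize(sub["rating"].to_numpy(), label=label))
            alpha_groups.append(summarize(sub["alpha_db"].to_numpy(), label=label))
    if len(groups) >= 2:
        res = anova_from_summary(groups)
        out["behavior_anova"] = asdict(res)
        out["behavior_posthoc"] = bonferroni_posthoc(groups)
        out["alpha_anova"] = asdict(anova_from_summary(alpha_groups))
    by_label = {g.label: g for g in alpha_groups}
    if "high" in by_label and "low" in by_label:
        hi, lo = by_label["high"], by_label["low"]
        t = ttest_from_summary(hi.mean, hi.sd, hi.n, lo.mean, lo.sd, lo.n)
        out["alpha_split_ttest"] = asdict(t)
    return out
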