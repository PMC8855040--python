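"""End-to-end orchestration: recordings -> features -> stats -> classification.

The stage order is fixed: preprocess, then the three feature families
(multifractal cumulants, multiscale entropy, PLI node strength) on the same
50 s epoch, then group statistics, then cross-validated classification.
Every output CSV carries the configuration hash so runs are traceable, and
a run is bit-for-bit reproducible from its config file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import connectivity as conn
from . import multifractal as mf
from . import stats as st
from .io import Recording, read_cohort_csv
from .mse import MSEParams, fast_scale_mean, mse_curve
from .preprocess import BANDS, BAND_BY_NAME, bandpass, relative_band_power, segment_for_pli, trim_select, zscore
from .synth import SynthSpec, generate_cohort

log = logging.getLogger("eegcomplex")

#: Feature sets evaluated by the classification stage: each single block,
#: then the pairwise combinations reported in the study design.
DEFAULT_FEATURE_SETS = (
    ("c1", ("c1",)),
    ("c2_abs", ("c2_abs",)),
    ("fast_entropy", ("fast_entropy",)),
    ("ns_delta", ("ns_delta",)),
    ("ns_theta", ("ns_theta",)),
    ("ns_alpha", ("ns_alpha",)),
    ("ns_beta", ("ns_beta",)),
    ("ns_gamma", ("ns_gamma",)),
    ("c1+c2_abs", ("c1", "c2_abs")),
    ("c1+ns_alpha", ("c1", "ns_alpha")),
    ("c2_abs+ns_alpha", ("c2_abs", "ns_alpha")),
    ("fast_entropy+ns_alpha", ("fast_entropy", "ns_alpha")),
)


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run."""

    output_dir: str = "run"
    input_dir: str | None = None  # cohort directory; None -> synthesise
    synth: dict = field(default_factory=dict)  # SynthSpec overrides
    mse: dict = field(default_factory=dict)  # MSEParams overrides
    wavelet: str = mf.DEFAULT_WAVELET
    fit_scale_range: tuple[int, int] | None = None
    n_components: int = 3
    repeats: int = 20
    folds: int = 5
    seed: int = 0
    feature_sets: list = field(default_factory=lambda: [list(fs) for fs in DEFAULT_FEATURE_SETS])
    with_stats: bool = True
    with_classification: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.fit_scale_range is not None:
            cfg.fit_scale_range = tuple(cfg.fit_scale_range)
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        # hash the scientific configuration only, so identical analyses in
        # different output directories share a hash
        payload = asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:12]


def compute_subject_features(
    recording: Recording,
    mse_params: MSEParams | None = None,
    wavelet: str = mf.DEFAULT_WAVELET,
    fit_scale_range: tuple[int, int] | None = None,
    keep_mse_curve: bool = False,
) -> dict:
    """All per-channel features of one subject from its raw recording.

    Broadband filter -> trim to the 50 s epoch -> z-score; the multifractal
    cumulants and the MSE run on the z-scored broadband epoch, the PLI on
    its ten 5 s segments, and the gamma relative power (covariate) on the
    un-z-scored epoch.
    """
    filtered = bandpass(recording)
    epoch = trim_select(filtered)
    labels = recording.channel_labels
    z = zscore(epoch.samples)

    cumulants = mf.channel_cumulants(z, wavelet, fit_scale_range)

    params = mse_params or MSEParams()
    profile = mse_curve(epoch, params)
    fast_mean = fast_scale_mean(profile, 1, min(5, params.max_scale))

    epochs = segment_for_pli(epoch)
    pli = conn.pli_matrix(epochs, BANDS)
    ns = conn.node_strength(pli)

    gamma_power = relative_band_power(epoch, BAND_BY_NAME["gamma"])

    row: dict = {"subject_id": recording.subject_id, "group": recording.group}
    for i, ch in enumerate(labels):
        row[f"c1_{ch}"] = cumulants[i, 0]
        row[f"c2_{ch}"] = cumulants[i, 1]
        row[f"c2abs_{ch}"] = abs(cumulants[i, 1])
        row[f"entropy_{ch}"] = fast_mean[i]
        for bi, band in enumerate(pli.bands):
            row[f"ns_{band}_{ch}"] = ns.values[bi, i]
        row[f"gamma_power_{ch}"] = gamma_power[i]
    out = {"row": row, "pli": pli}
    if keep_mse_curve:
        out["mse"] = profile
    else:
        out["mse_entropy"] = profile.entropy
    return out


def compute_feature_table(
    recordings: list[Recording],
    mse_params: MSEParams | None = None,
    wavelet: str = mf.DEFAULT_WAVELET,
    fit_scale_range: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Feature table plus the stacked PLI and MSE arrays for the stats stage.

    Returns (table, pli_values, mse_entropy) where ``pli_values`` is
    subjects x bands x channels x channels and ``mse_entropy`` is
    subjects x channels x scales.
    """
    rows, plis, mses = [], [], []
    for rec in recordings:
        t0 = time.perf_counter()
        result = compute_subject_features(rec, mse_params, wavelet, fit_scale_range)
        rows.append(result["row"])
        plis.append(result["pli"].values)
        mses.append(result["mse_entropy"])
        log.info("features: %s (%.2f s)", rec.subject_id, time.perf_counter() - t0)
    return pd.DataFrame(rows), np.stack(plis), np.stack(mses)


def _measure_block(table: pd.DataFrame, prefix: str, labels: tuple[str, ...]) -> np.ndarray:
    return table[[f"{prefix}{ch}" for ch in labels]].to_numpy(dtype=float)


def run_stats(
    table: pd.DataFrame,
    pli_values: np.ndarray,
    mse_entropy: np.ndarray,
    channel_labels: tuple[str, ...],
) -> dict[str, pd.DataFrame]:
    """Mixed ANOVAs, the gamma-power ANCOVA, post-hoc maps, and correlations."""
    groups = table["group"].to_numpy()
    is_old = groups == "older"
    covariate = _measure_block(table, "gamma_power_", channel_labels).mean(axis=1)

    anova_rows, ancova_rows = [], []

    def _collect(rows, results, measure):
        for res in results:
            rows.append(
                {
                    "measure": measure,
                    "effect": res.effect,
                    "F": res.F,
                    "p": res.p,
                    "partial_eta2": res.partial_eta2,
                    "df1": res.df[0],
                    "df2": res.df[1],
                    "epsilon": res.epsilon,
                }
            )

    per_channel_measures = {
        "c1": _measure_block(table, "c1_", channel_labels),
        "c2_abs": _measure_block(table, "c2abs_", channel_labels),
        "fast_entropy": _measure_block(table, "entropy_", channel_labels),
    }
    for band in (b.name for b in BANDS):
        per_channel_measures[f"ns_{band}"] = _measure_block(
            table, f"ns_{band}_", channel_labels
        )
    for measure, data in per_channel_measures.items():
        _collect(anova_rows, st.mixed_anova(data, groups, ("node",)), measure)
    if mse_entropy.shape[2] >= 2:
        _collect(
            anova_rows,
            st.mixed_anova(mse_entropy, groups, ("node", "scale")),
            "entropy_by_scale",
        )
    for measure in ("c1", "c2_abs", "fast_entropy", "ns_gamma"):
        _collect(
            ancova_rows,
            st.ancova_covariate(per_channel_measures[measure], groups, covariate, ("node",)),
            measure,
        )

    posthoc_frames = []
    for measure in ("c1", "c2_abs"):
        data = per_channel_measures[measure]
        res = st.posthoc_ttests(data[~is_old], data[is_old], expected_family=len(channel_labels))
        posthoc_frames.append(
            pd.DataFrame(
                {
                    "measure": measure,
                    "channel": list(channel_labels),
                    "t": res.t_values,
                    "p": res.raw_p,
                    "significant": res.significant,
                }
            )
        )
    n_scales = mse_entropy.shape[2]
    flat_mse = mse_entropy.reshape(len(table), -1)
    res = st.posthoc_ttests(
        flat_mse[~is_old], flat_mse[is_old], expected_family=len(channel_labels) * n_scales
    )
    posthoc_frames.append(
        pd.DataFrame(
            {
                "measure": "entropy",
                "channel": np.repeat(list(channel_labels), n_scales),
                "scale": np.tile(np.arange(1, n_scales + 1), len(channel_labels)),
                "t": res.t_values,
                "p": res.raw_p,
                "significant": res.significant,
            }
        )
    )
    ns_all = np.concatenate(
        [per_channel_measures[f"ns_{b.name}"] for b in BANDS], axis=1
    )
    res = st.posthoc_ttests(
        ns_all[~is_old], ns_all[is_old], expected_family=len(channel_labels) * len(BANDS)
    )
    posthoc_frames.append(
        pd.DataFrame(
            {
                "measure": "ns",
                "band": np.repeat([b.name for b in BANDS], len(channel_labels)),
                "channel": np.tile(list(channel_labels), len(BANDS)),
                "t": res.t_values,
                "p": res.raw_p,
                "significant": res.significant,
            }
        )
    )
    pair_idx = np.triu_indices(len(channel_labels), k=1)
    pli_pairs = pli_values[:, :, pair_idx[0], pair_idx[1]].reshape(len(table), -1)
    res = st.posthoc_ttests(
        pli_pairs[~is_old],
        pli_pairs[is_old],
        expected_family=st.family_size("pair_band", len(channel_labels), n_bands=len(BANDS)),
    )
    pair_labels = st.electrode_pair_labels(channel_labels)
    posthoc_frames.append(
        pd.DataFrame(
            {
                "measure": "pli",
                "band": np.repeat([b.name for b in BANDS], len(pair_labels)),
                "channel_a": np.tile([a for a, _ in pair_labels], len(BANDS)),
                "channel_b": np.tile([b for _, b in pair_labels], len(BANDS)),
                "t": res.t_values,
                "p": res.raw_p,
                "significant": res.significant,
            }
        )
    )

    spearman_rows = []
    for band in (b.name for b in BANDS):
        ns_block = per_channel_measures[f"ns_{band}"]
        for index_name in ("c1", "c2_abs"):
            ci = per_channel_measures[index_name]
            for gname, mask in (("younger", ~is_old), ("older", is_old)):
                r, corr = st.spearman_ns_complexity(ns_block[mask], ci[mask])
                for chi, ch in enumerate(channel_labels):
                    spearman_rows.append(
                        {
                            "band": band,
                            "index": index_name,
                            "group": gname,
                            "channel": ch,
                            "R": r[chi],
                            "p": corr.raw_p[chi],
                            "significant": corr.significant[chi],
                        }
                    )

    return {
        "anova": pd.DataFrame(anova_rows),
        "ancova": pd.DataFrame(ancova_rows),
        "posthoc": pd.concat(posthoc_frames, ignore_index=True),
        "spearman": pd.DataFrame(spearman_rows),
    }


def run_classification(
    table: pd.DataFrame,
    feature_sets: list,
    n_components: int = 3,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated AUC for each named feature set, shared fold seeds."""
    rows = []
    for name, blocks in feature_sets:
        spec = cls.FeatureSetSpec(name=name, blocks=tuple(blocks), n_components=n_components)
        X, y = cls.assemble_features(table, spec)
        roc = cls.cv_auc(
            X, y, n_components=n_components, repeats=repeats, folds=folds,
            seed=seed, name=name,
        )
        rows.append(
            {
                "feature_set": name,
                "auc_mean": roc.auc_mean,
                "auc_sd": roc.auc_sd,
                "repeats": repeats,
                "folds": folds,
            }
        )
        log.info("classify: %s AUC %.3f (SD %.3f)", name, roc.auc_mean, roc.auc_sd)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write all outputs under the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    if config.input_dir is not None:
        in_dir = Path(config.input_dir)
        if not in_dir.is_dir():
            raise FileNotFoundError(f"input directory {in_dir} does not exist")
        recordings = read_cohort_csv(in_dir)
    else:
        spec = SynthSpec(**{"seed": config.seed, **config.synth})
        recordings = generate_cohort(spec)
    log.info("cohort: %d recordings", len(recordings))

    mse_params = MSEParams(**config.mse)
    table, pli_values, mse_entropy = compute_feature_table(
        recordings, mse_params, config.wavelet, config.fit_scale_range
    )

    header = f"# config_hash: {config.config_hash}\n"

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)

    feature_cols = [c for c in table.columns if not c.startswith(("gamma_power_", "c2_"))
                    or c.startswith("c2abs_")]
    _write(table[feature_cols], "features.csv")
    _write(
        table[["subject_id", "group"] + [c for c in table.columns if c.startswith(("gamma_power_", "c2_")) and not c.startswith("c2abs_")]],
        "covariates.csv",
    )

    summary: dict = {
        "config_hash": config.config_hash,
        "n_subjects": len(recordings),
        "stages": ["preprocess", "features"],
    }

    if config.with_stats:
        labels = recordings[0].channel_labels
        tables = run_stats(table, pli_values, mse_entropy, labels)
        for name, frame in tables.items():
            _write(frame, f"{name}.csv")
        summary["stages"].append("stats")

    if config.with_classification:
        roc = run_classification(
            table,
            [tuple(fs) for fs in config.feature_sets],
            config.n_components,
            config.repeats,
            config.folds,
            config.seed,
        )
        _write(roc, "roc.csv")
        summary["stages"].append("classify")

    (out / "config.yaml").write_text(config.to_yaml())
    summary["elapsed_seconds"] = round(time.perf_counter() - t_start, 2)
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline finished in %.1f s -> %s", summary["elapsed_seconds"], out)
    return out
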