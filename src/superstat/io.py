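"""Data readers/writers, model configuration, and fixture generation.

CSV conventions: comma-separated, UTF-8, ``.`` decimal, mandatory header.
Trial/time indices are 1-based in files and 0-based in memory; the
translation happens here and only here.

DDM series files have columns ``trial,rt,choice,condition``; Poisson count
series have ``t,count``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import (
    LowLevelSpec,
    ModelSpec,
    ObservationSeries,
    SimulationRecord,
    TransitionSpec,
    ddm_model,
    poisson_random_walk_model,
    simulate_dataset,
)
from .priors import ConfigurationError, PriorSpec

__all__ = [
    "read_timeseries", "write_timeseries", "model_from_config",
    "load_model_file", "make_fixtures", "run_experiment", "PRESETS",
]


# ---------------------------------------------------------------------------
# series I/O
# ---------------------------------------------------------------------------

_DDM_COLS = ["trial", "rt", "choice", "condition"]
_POIS_COLS = ["t", "count"]


def read_timeseries(path: str | Path, schema: str) -> ObservationSeries:
    """Read and validate a series CSV (``schema`` is ``ddm`` or ``poisson``).

    Malformed files raise a data error naming the offending rows (1-based,
    excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema == "poisson":
        missing = [c for c in _POIS_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = df.index[counts.isna() | (counts < 0) | (counts % 1 != 0)] + 1
        if len(bad):
            raise ValueError(f"{path}: invalid counts in rows {list(bad)}")
        return ObservationSeries(kind="poisson", counts=counts.to_numpy(dtype=int))
    if schema == "ddm":
        required = ["trial", "rt", "choice"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        rt = pd.to_numeric(df["rt"], errors="coerce")
        choice = pd.to_numeric(df["choice"], errors="coerce")
        bad = df.index[rt.isna() | (rt <= 0)] + 1
        if len(bad):
            raise ValueError(f"{path}: invalid response times in rows {list(bad)}")
        bad = df.index[choice.isna() | ~choice.isin([0, 1])] + 1
        if len(bad):
            raise ValueError(f"{path}: invalid choices in rows {list(bad)}")
        if "condition" in df.columns:
            cond = pd.to_numeric(df["condition"], errors="coerce")
            bad = df.index[cond.isna() | (cond < 0) | (cond % 1 != 0)] + 1
            if len(bad):
                raise ValueError(f"{path}: invalid condition codes in rows {list(bad)}")
            cond = cond.to_numpy(dtype=int)
        else:
            cond = np.zeros(len(df), dtype=int)
        n_cond = int(cond.max()) + 1 if len(cond) else 1
        return ObservationSeries(
            kind="ddm", rt=rt.to_numpy(float), choice=choice.to_numpy(int),
            condition=cond, n_conditions=max(n_cond, 1),
        )
    raise ValueError(f"unknown schema {schema!r}")


def write_timeseries(series: ObservationSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if series.kind == "poisson":
        df = pd.DataFrame({"t": np.arange(1, len(series) + 1), "count": series.counts})
    else:
        df = pd.DataFrame({
            "trial": np.arange(1, len(series) + 1),
            "rt": series.rt, "choice": series.choice, "condition": series.condition,
        })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

PRESETS = {
    "poisson_random_walk": lambda **kw: poisson_random_walk_model(),
    "ddm_static": lambda **kw: ddm_model("static", **kw),
    "ddm_random_walk": lambda **kw: ddm_model("random_walk", **kw),
    "ddm_itv": lambda **kw: ddm_model("itv", **kw),
    "ddm_gp": lambda **kw: ddm_model("gp", **kw),
    "ddm_regime_switch": lambda **kw: ddm_model("regime_switch", **kw),
}


def model_from_config(cfg: dict) -> ModelSpec:
    """Build a :class:`ModelSpec` from a config mapping.

    Either ``preset: <name>`` (with optional ``n_conditions`` and
    ``switch_times``) or an explicit declaration with ``low_level``,
    ``transition`` and ``priors`` sections.  Prior overrides are accepted in
    both forms under ``priors.theta0`` and ``priors.eta``.
    """
    if "preset" in cfg:
        name = cfg["preset"]
        if name not in PRESETS:
            raise ConfigurationError(
                f"unknown model preset {name!r}; known: {sorted(PRESETS)}")
        kwargs = {}
        if name.startswith("ddm"):
            if "n_conditions" in cfg:
                kwargs["n_conditions"] = int(cfg["n_conditions"])
            if "switch_times" in cfg and name == "ddm_regime_switch":
                kwargs["switch_times"] = tuple(cfg["switch_times"])
        model = PRESETS[name](**kwargs)
    else:
        low_cfg = cfg["low_level"]
        trans_cfg = cfg["transition"]
        base = (poisson_random_walk_model() if low_cfg["kind"] == "poisson"
                else ddm_model(trans_cfg["kind"],
                               n_conditions=int(low_cfg.get("n_conditions", 1))))
        model = base
    for section, target in (("theta0", model.low.theta0_priors),
                            ("eta", model.transition.eta_priors)):
        for pname, pcfg in cfg.get("priors", {}).get(section, {}).items():
            if pname not in target:
                raise ConfigurationError(
                    f"prior override for unknown parameter {pname!r}")
            target[pname] = PriorSpec(pcfg["family"], dict(pcfg["params"]), name=pname)
    return model


def load_model_file(path: str | Path) -> ModelSpec:
    with open(path) as fh:
        return model_from_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_SCENARIOS = ("static", "itv", "random_walk", "regime_switch")


def _write_record(rec: SimulationRecord, stem: Path) -> list[Path]:
    write_timeseries(rec.series, stem.with_suffix(".series.csv"))
    truth = pd.DataFrame(rec.trajectory.values, columns=list(rec.trajectory.names))
    truth.insert(0, "t", np.arange(0, rec.trajectory.T + 1))
    truth.to_csv(stem.with_suffix(".truth.csv"), index=False)
    eta = pd.DataFrame([rec.eta.as_dict()]) if len(rec.eta.names) else pd.DataFrame()
    eta.to_csv(stem.with_suffix(".eta.csv"), index=False)
    return [stem.with_suffix(s) for s in (".series.csv", ".truth.csv", ".eta.csv")]


def make_fixtures(preset: str, seed: int, out_dir: str | Path,
                  count: int = 100, T: int | None = None) -> Path:
    """Generate the packaged benchmark data sets on disk.

    Presets: ``coal`` (one Poisson series, T=110), ``static-ddm-benchmark``
    (``count`` static-DDM series of T=100), ``simulation-study`` (one series
    per scenario — static, inter-trial variability, random walk, regime
    switch — at T=400), ``gp-ddm`` (one 4-condition GP-DDM series, T=400).
    Deterministic given ``seed``; a manifest records everything needed to
    reproduce the files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    ss = np.random.SeedSequence(seed)
    if preset == "coal":
        rec = simulate_dataset(poisson_random_walk_model(), T or 110,
                               int(ss.generate_state(1)[0] % 2**31))
        files += _write_record(rec, out / "coal")
    elif preset == "static-ddm-benchmark":
        seeds = ss.generate_state(count) % 2**31
        for i, s in enumerate(seeds):
            rec = simulate_dataset(ddm_model("static"), T or 100, int(s))
            files += _write_record(rec, out / f"static_{i:03d}")
    elif preset == "simulation-study":
        seeds = ss.generate_state(len(_SCENARIOS)) % 2**31
        for scen, s in zip(_SCENARIOS, seeds):
            rec = simulate_dataset(ddm_model(scen), T or 400, int(s))
            files += _write_record(rec, out / f"scenario_{scen}")
    elif preset == "gp-ddm":
        rec = simulate_dataset(ddm_model("gp", n_conditions=4), T or 400,
                               int(ss.generate_state(1)[0] % 2**31))
        files += _write_record(rec, out / "gp_ddm")
    else:
        raise ConfigurationError(f"unknown fixture preset {preset!r}")
    manifest = {
        "preset": preset, "seed": seed, "count": count, "T": T,
        "files": {f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


def run_experiment(config: dict, out_dir: str | Path) -> Path:
    """simulate -> train -> infer -> validate, with a reproducibility manifest.

    ``config`` holds ``model`` (mapping for :func:`model_from_config`),
    ``training`` (kwargs for TrainingConfig), ``seed``, ``n_eval`` and
    ``T_eval``.  Partial outputs are kept on failure; the manifest marks the
    failed stage.
    """
    from .neural import AmortizedFilter, TrainingConfig
    from .validation import recovery

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config, "stages": {}}
    path = out / "manifest.json"

    def _mark(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        path.write_text(json.dumps(manifest, indent=1, default=str))

    seed = int(config.get("seed", 0))
    try:
        model = model_from_config(config["model"])
        _mark("model", "ok")
        tc = TrainingConfig(seed=seed, **config.get("training", {}))
        af = AmortizedFilter(model, tc)
        af.train()
        af.save(out / "ckpt")
        _mark("train", "ok")
        n_eval = int(config.get("n_eval", 20))
        T_eval = int(config.get("T_eval", tc.T))
        records, posteriors = [], []
        for i in range(n_eval):
            rec = simulate_dataset(model, T_eval, seed + 10_000 + i)
            records.append(rec)
            posteriors.append(af.filter(rec.series, n_draws=500, seed=seed + i))
            _write_record(rec, out / f"eval_{i:03d}")
        _mark("simulate", "ok")
        rep = recovery(records, posteriors, scatter_at=[min(99, T_eval - 1) + 1])
        pd.DataFrame(rep.mae, columns=list(rep.param_names)).to_csv(
            out / "recovery_mae.csv", index_label="t")
        pd.DataFrame(rep.sd, columns=list(rep.param_names)).to_csv(
            out / "recovery_sd.csv", index_label="t")
        (out / "recovery_corr.json").write_text(json.dumps(
            {f"{p}@t{t}": v for (p, t), v in rep.correlation.items()}, indent=1))
        _mark("validate", "ok")
    except Exception as exc:  # record the failing stage, keep partial output
        stage = next((s for s in ("model", "train", "simulate", "validate")
                      if s not in manifest["stages"]), "unknown")
        _mark(stage, f"failed: {exc}")
        raise
    return out
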