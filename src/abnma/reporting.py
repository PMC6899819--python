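"""Reproducible runs: configuration, fitting bundles, comparison tables.

A :class:`RunConfig` names a data source, a model, and a chain regime; a
run writes everything needed to reproduce and audit it — retained draws,
summaries, autocorrelation diagnostics, the resolved configuration (with a
content hash of the input data), and a log.  All tabular outputs are CSV;
sidecars are JSON.  Plot rendering is out of scope: the comparison table is
the machine-readable twin of a forest plot.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hypodata
from .estimands import (
    EstimandRequest,
    conditional_contrast,
    external_target,
    marginal_contrast,
    marginal_mean,
)
from .mcmc import (
    ChainConfig,
    PosteriorDraws,
    autocorrelation,
    fit,
    summary_table,
)
from .models import ModelSpec
from .network import Network, load_corticosteroids, read_network, write_network

__all__ = ["RunConfig", "resolve_network", "cmd_fit", "cmd_compare", "cmd_estimand"]

#: autocorrelation threshold used in diagnostics reports
ACF_THRESHOLD = 0.2
ACF_LAGS = range(1, 21)


@dataclass
class RunConfig:
    """One reproducible fit: data source, model, chains, outputs."""

    data: str  # CSV path, "corticosteroids", or "scenario:<name>" e.g. 3b
    spec: ModelSpec = field(default_factory=lambda: ModelSpec(model=1))
    chains: ChainConfig = field(default_factory=ChainConfig)
    outdir: str | Path = "nma_run"
    estimands: list[EstimandRequest] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "data": str(self.data),
            "spec": self.spec.to_dict(),
            "chains": self.chains.to_dict(),
            "outdir": str(self.outdir),
            "estimands": [vars(e) for e in self.estimands],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["spec"] = ModelSpec.from_dict(d.get("spec", {"model": 1}))
        d["chains"] = ChainConfig.from_dict(d.get("chains", {}))
        d["estimands"] = [
            EstimandRequest(
                kind=e["kind"],
                treatments=tuple(e["treatments"]),
                link=e.get("link", "logit"),
                external_risk=e.get("external_risk"),
            )
            for e in d.get("estimands", [])
        ]
        return cls(**d)


def resolve_network(data: str) -> tuple[Network, str]:
    """Resolve a data-source string to a Network and its content hash."""
    if data == "corticosteroids":
        net = load_corticosteroids()
    elif data.startswith("scenario:"):
        name = data.split(":", 1)[1]
        spec = hypodata.ScenarioSpec(scenario=int(name[0]), subtype=name[1])
        net, _ = hypodata.generate(spec)
    else:
        net = read_network(data)
    csv = net.to_frame().to_csv(index=False)
    digest = hashlib.sha256(csv.encode()).hexdigest()[:16]
    return net, digest


def _diagnostics(draws: PosteriorDraws) -> dict:
    acf = {
        p: [autocorrelation(draws, p, lag) for lag in ACF_LAGS]
        for p in draws.parameters
    }
    worst_ok_lag = {}
    for p, series in acf.items():
        lag_ok = next(
            (
                lag
                for lag, v in zip(ACF_LAGS, series)
                if all(abs(w) < ACF_THRESHOLD for w in series[lag - 1 :])
            ),
            None,
        )
        worst_ok_lag[p] = lag_ok
    return {
        "autocorrelation_lags": list(ACF_LAGS),
        "autocorrelation": acf,
        "first_lag_below_threshold": worst_ok_lag,
        "threshold": ACF_THRESHOLD,
        "acceptance_rates": draws.acceptance,
    }


def _run_estimand(draws: PosteriorDraws, req: EstimandRequest):
    ts = req.treatments
    if req.kind == "conditional_logOR":
        return conditional_contrast(draws, ts[0], ts[1], scale="log")
    if req.kind == "conditional_OR":
        return conditional_contrast(draws, ts[0], ts[1], scale="or")
    if req.kind == "marginal_mean":
        return marginal_mean(draws, ts[0])
    if req.kind == "marginal_contrast":
        return marginal_contrast(draws, ts[0], ts[1], link=req.link)
    return external_target(draws, req.external_risk, ts[0], ts[1] if len(ts) > 1 else 1)


def cmd_fit(config: RunConfig) -> dict:
    """Fit one model and write the result bundle; returns the file map."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"# nma fit log  seed={config.chains.seed}",
        f"started {time.strftime('%Y-%m-%dT%H:%M:%S')}",
    ]
    net, digest = resolve_network(config.data)
    log_lines.append(f"data {config.data} sha256[:16]={digest} "
                     f"n_studies={net.n_studies} K={net.n_treatments}")
    log_lines.append(f"model: {config.spec.label}")
    t0 = time.perf_counter()
    draws = fit(config.spec, net, config.chains)
    log_lines.append(f"sampling finished in {time.perf_counter() - t0:.1f}s")

    files = {
        "network": outdir / "network.csv",
        "draws": outdir / "draws.csv",
        "draws_meta": outdir / "draws_meta.json",
        "summary": outdir / "summary.csv",
        "diagnostics": outdir / "diagnostics.json",
        "config": outdir / "resolved_config.json",
        "log": outdir / "run.log",
    }
    write_network(net, files["network"])
    draws.save(files["draws"], files["draws_meta"])
    summary = summary_table(draws)
    summary.to_csv(files["summary"], index=False)

    diag = _diagnostics(draws)
    bad = [
        p
        for p, lag in diag["first_lag_below_threshold"].items()
        if lag is None or lag > 8
    ]
    if bad:  # diagnostic warning, never a failure
        log_lines.append(
            f"WARNING: autocorrelation >= {ACF_THRESHOLD} beyond lag 8 "
            f"(post-thinning) for: {', '.join(bad)}"
        )
    with open(files["diagnostics"], "w") as fh:
        json.dump(diag, fh, indent=2)

    est_rows = []
    for req in config.estimands:
        s = _run_estimand(draws, req)
        est_rows.append(
            {
                "kind": req.kind,
                "treatments": "/".join(map(str, req.treatments)),
                "link": req.link,
                "median": s.median,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        )
    if est_rows:
        files["estimands"] = outdir / "estimands.csv"
        pd.DataFrame(est_rows).to_csv(files["estimands"], index=False)

    resolved = config.to_dict()
    resolved["data_sha256_16"] = digest
    with open(files["config"], "w") as fh:
        json.dump(resolved, fh, indent=2)
    with open(files["log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return files


def cmd_compare(
    configs: list[RunConfig],
    contrast: tuple[int, int],
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Fit several model variants on one network; tabulate one contrast.

    The machine-readable twin of a forest plot: one row per model variant
    with the posterior median and 95% CrI of the requested contrast.
    """
    if not configs:
        raise ValueError("no configurations supplied")
    digests = {resolve_network(c.data)[1] for c in configs}
    if len(digests) > 1:
        raise ValueError("all configurations must share the same network")
    rows = []
    for c in configs:
        net, _ = resolve_network(c.data)
        draws = fit(c.spec, net, c.chains)
        s = conditional_contrast(draws, contrast[0], contrast[1], scale="log")
        rows.append(
            {
                "model": c.spec.model,
                "form": c.spec.form,
                "heterogeneity": c.spec.heterogeneity,
                "label": c.spec.label,
                "contrast": f"{contrast[0]} vs {contrast[1]}",
                "median": s.median,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        )
    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out, index=False)
    return table


def cmd_estimand(
    draws_path, meta_path, req: EstimandRequest
) -> pd.DataFrame:
    draws = PosteriorDraws.load(draws_path, meta_path)
    s = _run_estimand(draws, req)
    return pd.DataFrame(
        [
            {
                "kind": req.kind,
                "treatments": "/".join(map(str, req.treatments)),
                "link": req.link,
                "median": s.median,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        ]
    )
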