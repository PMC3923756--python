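"""Scenario readers/writers and run reports.

A scenario on disk is a directory of small delimiter-separated tables, one
per parameter role, mirroring how such data is tabulated in practice:

``scenario.yaml``
    axis names and order, the diet fractions used for whole-diet totals,
    and optional constraint lines.
``signals.csv``
    one row per (group, fraction), one column per proxy.
``concentrations.csv``
    one row per group, one column per fraction.
``weights.csv``
    one row per proxy, one column per fraction.
``offsets.csv`` / ``consumer.csv``
    one row per proxy.

Cells are written ``mean(sd)`` — e.g. ``-9.2(0.5)`` — with a bare number
meaning sd = 0 (a fixed constant) and a dash meaning "not available" in the
signal table.  Percentages are stored as printed (0-100 scale); conversion
to proportions happens inside the model.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import PosteriorChains, diagnose
from .scenario import DietaryScenario, ScenarioError, validate_scenario

__all__ = ["read_scenario", "write_scenario", "write_report", "scenario_hash"]

_DASHES = {"-", "–", "—", "", "nan", "NaN"}
_NUM = r"(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?|inf"
_CELL = re.compile(rf"^\s*(?P<mean>[-+]?(?:{_NUM}))"
                   rf"\s*(?:\(\s*(?P<sd>{_NUM})\s*\))?\s*$")


def _parse_cell(raw, where: str) -> tuple[float, float] | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in _DASHES:
        return None
    m = _CELL.match(s)
    if not m:
        raise ScenarioError(f"cannot parse cell {s!r} in {where}; expected 'mean(sd)' or '-'")
    sd = float(m.group("sd")) if m.group("sd") else 0.0
    return float(m.group("mean")), sd


def _fmt_num(x: float) -> str:
    s = f"{x:g}"
    return s if float(s) == x else repr(float(x))  # keep exact round-trips


def _format_cell(mean: float, sd: float) -> str:
    if sd == 0.0:
        return _fmt_num(mean)
    return f"{_fmt_num(mean)}({_fmt_num(sd)})"


def _read_table(path: Path, index_cols: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing scenario table: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in index_cols if c not in df.columns]
    if missing:
        raise ScenarioError(f"{path.name}: missing column(s) {missing}")
    return df.set_index(index_cols)


def read_scenario(path) -> DietaryScenario:
    """Load and validate a scenario directory; raises on any violation."""
    path = Path(path)
    meta_path = path / "scenario.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    groups = [str(g) for g in meta["groups"]]
    fractions = [str(f) for f in meta["fractions"]]
    proxies = [str(p) for p in meta["proxies"]]
    nI, nJ, nK = len(groups), len(fractions), len(proxies)

    def fill(df, rows, cols, mean, sd, ok=None, what=""):
        for r_pos, r in enumerate(rows):
            for c_pos, c in enumerate(cols):
                try:
                    raw = df.loc[r, c]
                except KeyError as e:
                    raise ScenarioError(f"{what}: missing entry for {r!r} / {c!r}") from e
                cell = _parse_cell(raw, f"{what} [{r}, {c}]")
                if cell is None:
                    if ok is None:
                        raise ScenarioError(f"{what}: entry for {r!r} / {c!r} may not be blank")
                    continue
                mean[r_pos, c_pos], sd[r_pos, c_pos] = cell
                if ok is not None:
                    ok[r_pos, c_pos] = True

    sig = _read_table(path / "signals.csv", ["group", "fraction"])
    extra = set(map(tuple, sig.index)) - {(g, f) for g in groups for f in fractions}
    if extra:
        raise ScenarioError(f"signals.csv: unknown group/fraction rows {sorted(extra)}")
    signal_mean = np.zeros((nI, nJ, nK))
    signal_sd = np.zeros((nI, nJ, nK))
    signal_ok = np.zeros((nI, nJ, nK), bool)
    for (g, f), row in sig.iterrows():
        if g not in groups or f not in fractions:
            raise ScenarioError(f"signals.csv: unknown names {g!r}/{f!r}")
        i, j = groups.index(g), fractions.index(f)
        for p in proxies:
            if p not in sig.columns:
                raise ScenarioError(f"signals.csv: missing proxy column {p!r}")
            cell = _parse_cell(row[p], f"signals.csv [{g},{f},{p}]")
            if cell is not None:
                signal_mean[i, j, p_idx := proxies.index(p)] = cell[0]
                signal_sd[i, j, p_idx] = cell[1]
                signal_ok[i, j, p_idx] = True

    conc = _read_table(path / "concentrations.csv", ["group"])
    conc_mean = np.zeros((nI, nJ))
    conc_sd = np.zeros((nI, nJ))
    fill(conc, groups, fractions, conc_mean, conc_sd, what="concentrations.csv")

    wgt = _read_table(path / "weights.csv", ["proxy"])
    weight_mean = np.zeros((nK, nJ))
    weight_sd = np.zeros((nK, nJ))
    fill(wgt, proxies, fractions, weight_mean, weight_sd, what="weights.csv")

    off = _read_table(path / "offsets.csv", ["proxy"])
    offset_mean = np.zeros((nK, 1))
    offset_sd = np.zeros((nK, 1))
    fill(off, proxies, ["offset"], offset_mean, offset_sd, what="offsets.csv")

    cons = _read_table(path / "consumer.csv", ["proxy"])
    consumer_mean = np.zeros((nK, 1))
    consumer_sd = np.zeros((nK, 1))
    fill(cons, proxies, ["signal"], consumer_mean, consumer_sd, what="consumer.csv")

    scenario = DietaryScenario(
        name=str(meta.get("name", path.name)),
        groups=groups, fractions=fractions, proxies=proxies,
        signal_mean=signal_mean, signal_sd=signal_sd, signal_ok=signal_ok,
        conc_mean=conc_mean, conc_sd=conc_sd,
        weight_mean=weight_mean.T, weight_sd=weight_sd.T,
        offset_mean=offset_mean[:, 0], offset_sd=offset_sd[:, 0],
        consumer_mean=consumer_mean[:, 0], consumer_sd=consumer_sd[:, 0],
        diet_fractions=tuple(meta.get("diet_fractions") or fractions),
        constraints=tuple(meta.get("constraints") or ()),
    )
    problems = validate_scenario(scenario)
    if problems:
        raise ScenarioError(
            f"invalid scenario in {path}:\n  " + "\n  ".join(problems))
    return scenario


def write_scenario(scenario: DietaryScenario, path) -> Path:
    """Write a scenario directory in the format read by :func:`read_scenario`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "name": scenario.name,
        "groups": list(scenario.groups),
        "fractions": list(scenario.fractions),
        "proxies": list(scenario.proxies),
        "diet_fractions": list(scenario.diet_fractions),
        "constraints": list(scenario.constraints),
    }
    (path / "scenario.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    rows = []
    for i, g in enumerate(scenario.groups):
        for j, f in enumerate(scenario.fractions):
            if not scenario.signal_ok[i, j, :].any():
                continue
            row = {"group": g, "fraction": f}
            for k, p in enumerate(scenario.proxies):
                row[p] = (_format_cell(scenario.signal_mean[i, j, k], scenario.signal_sd[i, j, k])
                          if scenario.signal_ok[i, j, k] else "-")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path / "signals.csv", index=False)

    pd.DataFrame(
        [{"group": g, **{f: _format_cell(scenario.conc_mean[i, j], scenario.conc_sd[i, j])
                         for j, f in enumerate(scenario.fractions)}}
         for i, g in enumerate(scenario.groups)]
    ).to_csv(path / "concentrations.csv", index=False)

    pd.DataFrame(
        [{"proxy": p, **{f: _format_cell(scenario.weight_mean[j, k], scenario.weight_sd[j, k])
                         for j, f in enumerate(scenario.fractions)}}
         for k, p in enumerate(scenario.proxies)]
    ).to_csv(path / "weights.csv", index=False)

    pd.DataFrame(
        [{"proxy": p, "offset": _format_cell(scenario.offset_mean[k], scenario.offset_sd[k])}
         for k, p in enumerate(scenario.proxies)]
    ).to_csv(path / "offsets.csv", index=False)

    pd.DataFrame(
        [{"proxy": p, "signal": _format_cell(scenario.consumer_mean[k], scenario.consumer_sd[k])}
         for k, p in enumerate(scenario.proxies)]
    ).to_csv(path / "consumer.csv", index=False)
    return path


def scenario_hash(scenario: DietaryScenario) -> str:
    """Stable content hash of every table in a scenario."""
    h = hashlib.sha256()
    h.update(repr((scenario.groups, scenario.fractions, scenario.proxies,
                   scenario.diet_fractions, scenario.constraints)).encode())
    for arr in (scenario.signal_mean, scenario.signal_sd, scenario.signal_ok,
                scenario.conc_mean, scenario.conc_sd, scenario.weight_mean,
                scenario.weight_sd, scenario.offset_mean, scenario.offset_sd,
                scenario.consumer_mean, scenario.consumer_sd):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def write_report(summary: pd.DataFrame, chains: PosteriorChains, config, outdir,
                 write_draws: bool = True) -> Path:
    """Write the posterior report: summary table, thinned draws, run manifest.

    ``summary.csv`` keeps full precision; ``summary.txt`` is the same table
    rendered with display rounding.  The manifest records the seed, sampler
    configuration, scenario hash and convergence flags so a run can be
    reproduced bitwise.
    """
    if summary.empty or chains.n_draws == 0:
        raise ValueError("cannot write a report for an empty posterior")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "summary.csv")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(summary.round(3).to_string())
        fh.write("\n")
    if write_draws:
        chains.to_frame().to_csv(outdir / "draws.csv", index=False)
    diag = diagnose(chains)
    manifest = {
        "sampler": asdict(config),
        "n_draws_per_chain": int(chains.n_draws),
        "acceptance": np.round(chains.acceptance, 4).tolist(),
        "flagged_parameters": diag.index[diag["flagged"]].tolist(),
        "package": "dietmix",
    }
    target = chains.target
    if hasattr(target, "scenario"):
        manifest["scenario"] = target.scenario.name
        manifest["scenario_sha256"] = scenario_hash(target.scenario)
        manifest["constraints"] = [c.text for c in target.constraints]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
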