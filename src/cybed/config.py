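"""TOML configuration loading for models, schedules and scenarios.

Model files use ``[taxon.<name>]`` sections with ``r``, ``K`` and an
optional ``interactions`` sub-table, plus a ``[schedule]`` section
(``T``, ``d``, ``n_cycles``, ``N_min``).  Scenario files use
``[scenario.<label>]`` (``s``, ``diet_only``) and optional
``[response.<taxon>]`` sections with piecewise-linear knots.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .bedding import ResponseCurve, SoilednessScenario
from .dynamics import CycleSchedule, TaxonParams
from .errors import ConfigurationError

__all__ = [
    "load_toml",
    "parse_model",
    "parse_scenarios",
    "load_model_config",
    "load_scenario_config",
]


def load_toml(path: str | Path) -> dict:
    try:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"malformed TOML in {path}: {exc}") from exc


def _require(section: dict, key: str, where: str):
    if key not in section:
        raise ConfigurationError(f"missing key {key!r} in {where}")
    return section[key]


def parse_model(doc: dict) -> tuple[list[TaxonParams], CycleSchedule]:
    """Parse taxa and schedule from a loaded model document."""
    taxa_doc = doc.get("taxon")
    if not taxa_doc:
        raise ConfigurationError("model config needs at least one [taxon.<name>] section")
    responses = {
        name: _parse_response(sec, f"[response.{name}]")
        for name, sec in doc.get("response", {}).items()
    }
    taxa = []
    for name, sec in taxa_doc.items():
        taxa.append(
            TaxonParams(
                name=name,
                r=float(_require(sec, "r", f"[taxon.{name}]")),
                K=float(_require(sec, "K", f"[taxon.{name}]")),
                interactions={k: float(v) for k, v in sec.get("interactions", {}).items()},
                substrate_response=responses.get(name),
            )
        )
    sched = doc.get("schedule", {})
    schedule = CycleSchedule(
        T=float(sched.get("T", 10.0)),
        d=float(sched.get("d", 0.01)),
        n_cycles=int(sched.get("n_cycles", 20)),
        N_min=float(sched.get("N_min", 1.0)),
    )
    return taxa, schedule


def _parse_response(sec: dict, where: str) -> ResponseCurve:
    def knots(key: str, default):
        raw = sec.get(key, default)
        try:
            return tuple((float(s), float(m)) for s, m in raw)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad knot list {key!r} in {where}") from exc

    return ResponseCurve(
        r_knots=knots("r_knots", ((0.0, 1.0), (1.0, 1.0))),
        k_knots=knots("k_knots", ((0.0, 1.0), (1.0, 1.0))),
        diet_only_r=float(sec.get("diet_only_r", 1.0)),
        diet_only_k=float(sec.get("diet_only_k", 1.0)),
    )


def parse_scenarios(doc: dict) -> dict[str, SoilednessScenario]:
    scen_doc = doc.get("scenario")
    if not scen_doc:
        raise ConfigurationError("scenario config needs [scenario.<label>] sections")
    return {
        label: SoilednessScenario(
            label=label,
            s=float(sec.get("s", 0.0)),
            diet_only=bool(sec.get("diet_only", False)),
        )
        for label, sec in scen_doc.items()
    }


def load_model_config(path: str | Path) -> tuple[list[TaxonParams], CycleSchedule]:
    return parse_model(load_toml(path))


def load_scenario_config(path: str | Path) -> dict[str, SoilednessScenario]:
    return parse_scenarios(load_toml(path))
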