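"""Config-file parsing for the command-line interface.

A single YAML (or JSON; YAML is a superset) document describes a
calculation:

.. code-block:: yaml

    design:
      kind: stepped_wedge         # or parallel / crossover / schematic
      sequences: 3
      clusters_per_sequence: [4, 4, 4]
      m: 10
    components:
      model: block_exchangeable   # or decay
      sigma2: 25
      rho: 0.33
      pi: 0.9
      tau: 0.7
    scheme:
      kind: constant_churn        # closed_population / beta_churn /
      chi: 0.0                    # in_for_p / custom
    effect:
      theta: 2
      alpha: 0.05
      target_power: 0.9           # sample-size mode only

``design.kind: schematic`` takes an inline ``matrix`` (list of 0/1 rows) or
a ``csv`` path as written by :func:`opencohort.designs.write_design`.
"""

from __future__ import annotations

import numpy as np
import yaml

from .components import BlockExchangeableComponents, DecayComponents
from .designs import TrialDesign, stepped_wedge, parallel_design, cluster_crossover, read_design
from .power import PowerQuery
from .schemes import (BetaChurn, ClosedPopulation, ConstantChurn, CustomChurn,
                      InForP)

__all__ = [
    "load_config",
    "design_from_config",
    "components_from_config",
    "scheme_from_config",
    "query_from_config",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def design_from_config(cfg: dict) -> TrialDesign:
    d = dict(cfg["design"])
    kind = d.pop("kind", "stepped_wedge")
    m = int(d.get("m", 1))
    cps = d.get("clusters_per_sequence")
    if kind == "stepped_wedge":
        return stepped_wedge(d["sequences"], tuple(cps) if cps else None, m)
    if kind == "parallel":
        return parallel_design(d["periods"], tuple(cps or (1, 1)), m)
    if kind == "crossover":
        return cluster_crossover(tuple(cps or (1, 1)), m)
    if kind == "schematic":
        if "csv" in d:
            return read_design(d["csv"], d.get("config"),
                               tuple(cps) if cps else None, m)
        X = np.asarray(d["matrix"])
        return TrialDesign(X, tuple(cps or (1,) * X.shape[0]), m)
    raise ValueError(f"unknown design kind {kind!r}")


def components_from_config(cfg: dict):
    c = dict(cfg["components"])
    model = c.pop("model", "block_exchangeable")
    if model == "block_exchangeable":
        return BlockExchangeableComponents(
            sigma2=c["sigma2"], rho=c["rho"],
            pi=c.get("pi", 1.0), tau=c.get("tau", 0.0))
    if model == "decay":
        return DecayComponents(
            sigma2=c["sigma2"], rho=c["rho"],
            pi_d=c.get("pi_d", 1.0), tau_d=c.get("tau_d", 0.0))
    raise ValueError(f"unknown variance-component model {model!r}")


def scheme_from_config(cfg: dict):
    s = dict(cfg["scheme"])
    kind = s.pop("kind")
    if kind == "constant_churn":
        return ConstantChurn(s["chi"])
    if kind == "closed_population":
        return ClosedPopulation(s["M"])
    if kind == "beta_churn":
        return BetaChurn(s["alpha"], s["beta"])
    if kind == "in_for_p":
        return InForP(s["p"])
    if kind == "custom":
        return CustomChurn(np.asarray(s["table"], dtype=float))
    raise ValueError(f"unknown scheme kind {kind!r}")


def query_from_config(cfg: dict) -> PowerQuery:
    e = cfg["effect"]
    return PowerQuery(theta=e["theta"], alpha=e.get("alpha", 0.05),
                      target_power=e.get("target_power"))
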