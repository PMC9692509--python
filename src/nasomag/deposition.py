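"""Delivery-efficiency accounting and protocol comparison.

Delivery efficiency is the percentage of released particles that deposit on
the olfactory region, out of everything released (SUSPENDED particles count
in the denominator but never the numerator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .airflow import solve_flow
from .errors import AccountingError, IncompleteRunError
from .geometry import RegionLabel, build_surrogate
from .magnetics import protocol_layout
from .tracing import ParticleStatus, default_release, release_line, trace

__all__ = [
    "DepositionSummary",
    "delivery_efficiency",
    "deposition_summary",
    "compare_protocols",
]


@dataclass
class DepositionSummary:
    """Per-protocol terminal-state bookkeeping.

    ``status_counts`` maps ParticleStatus name -> count; ``region_counts``
    maps RegionLabel name -> deposited/escaped-through count.  Efficiency
    is in percent of released particles; None when nothing was released.
    """

    n_released: int
    status_counts: dict
    region_counts: dict
    delivery_efficiency: float | None
    protocol: int | None = None
    config_hash: str | None = None

    @property
    def conserved(self) -> bool:
        return sum(self.status_counts.values()) == self.n_released

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "n_released": self.n_released,
            "status_counts": dict(self.status_counts),
            "region_counts": dict(self.region_counts),
            "delivery_efficiency_pct": self.delivery_efficiency,
            "config_hash": self.config_hash,
        }


def _require_terminal(states):
    for s in states:
        if s.status is ParticleStatus.IN_FLIGHT:
            raise IncompleteRunError(
                f"particle {s.particle_id} is still in flight; "
                "trace to termination before analysing deposition"
            )


def delivery_efficiency(states, region: RegionLabel = RegionLabel.OLFACTORY
                        ) -> float:
    """100 x (#DEPOSITED on ``region``) / (#released)."""
    _require_terminal(states)
    if not states:
        raise IncompleteRunError("no particles released")
    hits = sum(
        1 for s in states
        if s.status is ParticleStatus.DEPOSITED and s.region == region
    )
    return 100.0 * hits / len(states)


def deposition_summary(states, domain, protocol=None,
                       config_hash=None) -> DepositionSummary:
    """Histogram terminal states by status and boundary region.

    Deposited particles without a recorded region are mapped through the
    nearest boundary segment; a deposited particle farther than one grid
    cell from any boundary is an accounting error.
    """
    _require_terminal(states)
    status_counts = {st.name: 0 for st in ParticleStatus if st
                     is not ParticleStatus.IN_FLIGHT}
    region_counts = {lab.name: 0 for lab in RegionLabel}
    for s in states:
        status_counts[s.status.name] += 1
        if s.status is ParticleStatus.SUSPENDED:
            continue
        region = s.region
        if region is None:
            d, lab = domain.distance_to_boundary(s.position[None, :])
            if d[0] > domain.grid_spacing:
                raise AccountingError(
                    f"terminal particle {s.particle_id} at {s.position} is "
                    f"{d[0]:.3g} m from the nearest boundary"
                )
            region = RegionLabel(int(lab[0]))
        region_counts[region.name] += 1
    eff = (delivery_efficiency(states) if states else None)
    return DepositionSummary(
        n_released=len(states),
        status_counts=status_counts,
        region_counts=region_counts,
        delivery_efficiency=eff,
        protocol=protocol,
        config_hash=config_hash,
    )


def compare_protocols(config) -> pd.DataFrame:
    """Run the full pipeline per protocol on a shared domain and flow field.

    The airflow is magnet-independent, so it is solved once and reused for
    every protocol.  A magnet-free baseline row (protocol 0) is included
    when the config requests it.  Returns one row per protocol with the
    efficiency and per-region/status counts.
    """
    domain = build_surrogate(config.geometry)
    flow = solve_flow(domain, config.flow)
    rows = []
    for summary, _states in run_protocols(config, domain, flow):
        row = {
            "protocol": summary.protocol,
            "n_released": summary.n_released,
            "delivery_efficiency_pct": summary.delivery_efficiency,
        }
        row.update({f"n_{k.lower()}": v for k, v in summary.status_counts.items()})
        row.update({f"n_on_{k.lower()}": v for k, v in summary.region_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def run_protocols(config, domain, flow):
    """Trace every configured protocol (0 = magnet-free baseline); returns a
    list of (DepositionSummary, terminal states) pairs."""
    results = []
    protocols = list(config.protocols)
    if config.include_baseline and 0 not in protocols:
        protocols = [0] + protocols
    for proto in protocols:
        if proto == 0:
            magnets = []
            spec = default_release(domain, protocol=config.baseline_release,
                                   count=config.particle_count,
                                   line_length=config.release_length)
        else:
            magnets = protocol_layout(proto, distance=config.magnet_distance,
                                      center_yz=config.magnet_center_yz)
            spec = default_release(domain, protocol=proto,
                                   count=config.particle_count,
                                   line_length=config.release_length)
        if config.jitter_seed is not None:
            spec = type(spec)(count=spec.count, start=spec.start, end=spec.end,
                              x_offset=spec.x_offset,
                              jitter_seed=config.jitter_seed + proto)
        particles = release_line(spec, domain)
        terminal = trace(particles, flow, magnets, domain, config.particle,
                         config.trace, x_offset=spec.x_offset)
        results.append((
            deposition_summary(terminal, domain, protocol=proto,
                               config_hash=config.content_hash()),
            terminal,
        ))
    return results
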