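"""Quantitative read-outs: gradient metric, ODE-vs-PDE deviation, regime check.

The gradient metric is the maximum relative variation of a concentration
field at a time point, (max - min)/max over the PDE domain; for P1 fields
the extrema sit at nodes, so a nodal scan is exact.  The "deviation to the
well-mixed model" of a trajectory is the absolute difference between the
volume mean of each PDE species and the matching species of the well-mixed
companion ODE system integrated independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fem import Trajectory, l2_norm
from .model import ModelDefinition, ModelError, lumped_mass_vector


class DiagnosticsError(ValueError):
    pass


def max_relative_variation(values: np.ndarray) -> float:
    """(max - min)/max of a nodal concentration field; requires max > 0."""
    values = np.asarray(values, dtype=float)
    mx = float(values.max())
    if mx <= 0:
        raise DiagnosticsError(
            f"maximum relative variation undefined for max(field) = {mx:.3e} <= 0"
        )
    return float((mx - values.min()) / mx)


def variation_series(traj: Trajectory, species: str,
                     times: np.ndarray | None = None) -> np.ndarray:
    """Max relative variation of one species at each (or given) output time.

    Times where the field maximum is not positive yield NaN rather than an
    error, so early all-zero transients can be plotted/compared safely.
    """
    states = traj.states if times is None else traj.sample(times)
    out = np.empty(len(states))
    for k, s in enumerate(states):
        vals = s.fields[species]
        mx = float(vals.max())
        out[k] = (mx - float(vals.min())) / mx if mx > 0 else np.nan
    return out


def regime_ratio(D: float, L: float, k: float) -> tuple[float, str]:
    """Dimensionless D/(L^2 k): gradients matter when the ratio is << 1.

    Returns the ratio and an advisory label ('spatial model recommended'
    below 0.1, 'well-mixed adequate' above 10, 'borderline' between).
    """
    if L <= 0 or k <= 0:
        raise DiagnosticsError("L and k must be positive")
    if D < 0:
        raise DiagnosticsError("D must be nonnegative")
    ratio = D / (L * L * k)
    if ratio < 0.1:
        label = "spatial model recommended"
    elif ratio > 10.0:
        label = "well-mixed adequate"
    else:
        label = "borderline"
    return float(ratio), label


def ode_pde_deviation(traj: Trajectory, model: ModelDefinition | None = None,
                      times: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """|volume mean of PDE species - well-mixed companion| per output time.

    The companion replaces every PDE field by its volume average and every
    boundary flux by the area-scaled exchange term, and is integrated with
    an independent stiff integrator (see verification.wellmixed_oracle).
    Raises ``ModelError`` naming the obstruction when no companion is
    derivable (explicitly space-dependent rates).
    """
    from .verification import wellmixed_oracle

    model = model or traj.model
    times = traj.times if times is None else np.asarray(times, dtype=float)
    companion = wellmixed_oracle(model, times)
    w = lumped_mass_vector(model.mesh)
    vol = w.sum()
    states = traj.sample(times)
    out = {}
    for name in model.pde_names:
        means = np.array([float(w @ s.fields[name]) / vol for s in states])
        out[name] = np.abs(means - companion[name])
    for name in model.ode_names:
        series = np.interp(times, traj.times, traj.ode_series(name))
        out[name] = np.abs(series - companion[name])
    return out


@dataclass
class DiagnosticsReport:
    """Per-run quantitative summary."""

    times: np.ndarray
    variation: dict[str, np.ndarray]
    deviation: dict[str, np.ndarray] | None
    regime: dict[str, float] | None
    activated_counts: np.ndarray | None
    l2_norms: dict[str, np.ndarray]
    notes: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        data = {"t": self.times}
        for name, series in self.variation.items():
            data[f"variation_{name}"] = series
        if self.deviation:
            for name, series in self.deviation.items():
                data[f"deviation_{name}"] = series
        for name, series in self.l2_norms.items():
            data[f"l2_{name}"] = series
        if self.activated_counts is not None:
            data["activated_cells"] = self.activated_counts
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def summary_text(self) -> str:
        lines = ["diagnostics summary", "==================="]
        for name, series in self.variation.items():
            finite = series[np.isfinite(series)]
            if finite.size:
                lines.append(
                    f"max relative variation of {name}: "
                    f"{100 * float(np.nanmax(series)):.2f} % (peak over time)"
                )
        if self.deviation:
            for name, series in self.deviation.items():
                lines.append(
                    f"peak deviation to the well-mixed model, {name}: "
                    f"{float(np.max(series)):.4g}"
                )
        if self.regime:
            lines.append(
                "regime ratio D/(L^2 k) = "
                f"{self.regime['ratio']:.4g} ({self.regime['label']})"
            )
        if self.activated_counts is not None:
            lines.append(f"activated cells at final time: {int(self.activated_counts[-1])}")
        for key, val in self.notes.items():
            lines.append(f"{key}: {val}")
        return "\n".join(lines) + "\n"

    def write(self, directory, basename: str = "diagnostics") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_csv(directory / f"{basename}.csv")
        (directory / f"{basename}.txt").write_text(self.summary_text())


def build_report(traj: Trajectory, deviation: bool = True,
                 regime: tuple[float, float, float] | None = None,
                 activation_threshold: float | None = None) -> DiagnosticsReport:
    """Assemble the standard read-outs for one trajectory.

    ``regime`` optionally passes (D, L, k) for the regime criterion;
    ``activation_threshold`` enables activated-cell counting for models
    carrying per-cell receptor ODEs (lattice runs).
    """
    model = traj.model
    times = traj.times
    variation = {name: variation_series(traj, name) for name in model.pde_names}
    l2 = {
        name: np.array([l2_norm(model.mesh, s.fields[name]) for s in traj.states])
        for name in model.pde_names
    }
    dev = None
    if deviation:
        try:
            dev = ode_pde_deviation(traj)
        except ModelError:
            dev = None
    reg = None
    if regime is not None:
        ratio, label = regime_ratio(*regime)
        reg = {"ratio": ratio, "label": label, "D": regime[0], "L": regime[1], "k": regime[2]}
    counts = None
    if activation_threshold is not None:
        from .pathways import count_activated

        counts = count_activated(traj, activation_threshold)
    return DiagnosticsReport(
        times=times,
        variation=variation,
        deviation=dev,
        regime=reg,
        activated_counts=counts,
        l2_norms=l2,
    )
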