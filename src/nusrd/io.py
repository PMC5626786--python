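"""Flat-file formats: spectra (text header + raw float64), model dumps.

The schedule (nuslist), peak/intensity tables and curve/report CSVs live
next to the code that produces them; this module holds the bulkier binary
spectrum container and the decomposition-model dump used for inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .acquisition import GridSpec
from .reconstruct import DecompositionModel, SpectrumSeries
from .systems import CpmgSeriesSpec

__all__ = [
    "write_spectrum_series",
    "read_spectrum_series",
    "write_model_dump",
]

_MAGIC = "nusrd-spectrum-v1"


def write_spectrum_series(series: SpectrumSeries, path) -> None:
    """One file: a JSON text header line, then raw little-endian float64."""
    header = {
        "magic": _MAGIC,
        "shape": list(series.values.shape),
        "axes_hz": [ax.tolist() for ax in series.axes_hz],
        "obs_mhz": list(series.obs_mhz),
        "provenance": series.provenance,
        "nu_hz": list(series.spec.nu_hz),
        "t_relax": series.spec.t_relax,
        "field_tesla": series.spec.field_tesla,
        "nucleus": series.spec.nucleus,
        "grid": {
            "n_direct": series.grid.n_direct,
            "sw_direct_hz": series.grid.sw_direct_hz,
            "n_indirect": list(series.grid.n_indirect),
            "sw_indirect_hz": list(series.grid.sw_indirect_hz),
            "field_tesla": series.grid.field_tesla,
            "nuclei": list(series.grid.nuclei),
        },
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode())
        fh.write(np.ascontiguousarray(series.values, dtype="<f8").tobytes())


def read_spectrum_series(path) -> SpectrumSeries:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        if header.get("magic") != _MAGIC:
            raise ValueError(f"{path}: not a nusrd spectrum file")
        data = np.frombuffer(fh.read(), dtype="<f8").reshape(header["shape"])
    g = header["grid"]
    grid = GridSpec(
        n_direct=g["n_direct"],
        sw_direct_hz=g["sw_direct_hz"],
        n_indirect=tuple(g["n_indirect"]),
        sw_indirect_hz=tuple(g["sw_indirect_hz"]),
        field_tesla=g["field_tesla"],
        nuclei=tuple(g["nuclei"]),
    )
    spec = CpmgSeriesSpec(
        nu_hz=tuple(header["nu_hz"]),
        t_relax=header["t_relax"],
        field_tesla=header["field_tesla"],
        nucleus=header["nucleus"],
    )
    return SpectrumSeries(
        values=data.copy(),
        axes_hz=[np.array(ax) for ax in header["axes_hz"]],
        obs_mhz=tuple(header["obs_mhz"]),
        grid=grid,
        spec=spec,
        provenance=header["provenance"],
    )


def write_model_dump(model: DecompositionModel, path) -> None:
    """Structured text dump of a fitted decomposition for inspection."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# co-MDD model: {model.n_components} components, "
                 f"lambda={model.lambda_reg}, iters={model.n_iter_run}, "
                 f"converged={model.converged}, residual={model.rel_residual:.3e}\n")
        fh.write("# amplitudes (plane x component)\n")
        np.savetxt(fh, model.amplitudes, fmt="%.6e")
        fh.write("# direct shapes |V| (freq point x component)\n")
        np.savetxt(fh, np.abs(model.shape_direct), fmt="%.6e")
        for d, f in enumerate(model.shapes_indirect):
            fh.write(f"# indirect dim {d} shapes |V| (time point x component)\n")
            np.savetxt(fh, np.abs(f), fmt="%.6e")
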