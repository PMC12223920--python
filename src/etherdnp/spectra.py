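"""Data model and IO for 1D NMR spectra and saturation-recovery series.

The central container is :class:`Spectrum1D`: a calibrated chemical-shift
axis (ppm, stored strictly decreasing, the usual NMR display convention),
a real intensity vector and acquisition metadata.  Spectra can be read from
Bruker TopSpin processed-data directories (the ``procs`` parameter file plus
the ``1r``/``1i`` arrays) or from a plain two-column text interchange format
with a ``# key: value`` metadata header.

All ppm windows throughout the package are given as ``(high_ppm, low_ppm)``
pairs, matching how spectral regions are quoted in the field
(e.g. "90.1-80.4 ppm").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "Spectrum1D",
    "RelaxationCurve",
    "SpectrumFormatError",
    "read_bruker_processed",
    "write_internal",
    "read_internal",
    "write_curve",
    "read_curve",
    "ppm_to_index",
]


class SpectrumFormatError(ValueError):
    """Raised when an on-disk dataset is missing or malformed."""


@dataclass
class AcquisitionMeta:
    """Acquisition metadata carried alongside a spectrum.

    Parameters
    ----------
    spectrometer_freq_13C : float
        13C Larmor frequency in MHz (e.g. 100.6 on a 400-MHz magnet).
    mas_rate : float
        Magic-angle-spinning rate in kHz.
    temperature : float
        Sample temperature in K (~104 K under DNP conditions).
    n_scans : int
        Number of co-added scans.
    microwaves_on : bool
        Whether the gyrotron microwaves were on (DNP) or off (Boltzmann).
    relaxation_delay : float
        Recycle delay between scans, in s.
    label : str
        Free-text sample / experiment label.
    """

    spectrometer_freq_13C: float = 100.6
    mas_rate: float = 10.0
    temperature: float = 104.0
    n_scans: int = 1
    microwaves_on: bool = True
    relaxation_delay: float = 4.3
    label: str = ""

    def __post_init__(self) -> None:
        if self.spectrometer_freq_13C <= 0:
            raise ValueError("spectrometer_freq_13C must be > 0")
        if self.mas_rate < 0:
            raise ValueError("mas_rate must be >= 0")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")


@dataclass
class Spectrum1D:
    """A processed 1D spectrum on a uniform, strictly decreasing ppm axis.

    ``intensity_imag`` optionally carries the imaginary (dispersive) part so
    that zero/first-order phase correction can be applied exactly; most
    processed Bruker datasets provide it as the ``1i`` file.
    """

    ppm_axis: np.ndarray
    intensity: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    intensity_imag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm_axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm_axis and intensity must be 1-D")
        if self.ppm_axis.size != self.intensity.size:
            raise ValueError("ppm_axis and intensity must have equal length")
        if self.ppm_axis.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm_axis must be strictly decreasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite everywhere")
        if self.intensity_imag is not None:
            self.intensity_imag = np.asarray(self.intensity_imag, dtype=float)
            if self.intensity_imag.shape != self.intensity.shape:
                raise ValueError("imaginary part must match intensity shape")

    @property
    def n_points(self) -> int:
        return self.ppm_axis.size

    def copy(self, intensity: np.ndarray | None = None,
             intensity_imag: np.ndarray | None = None) -> "Spectrum1D":
        """Shallow-copy metadata and axis, optionally replacing data."""
        return Spectrum1D(
            ppm_axis=self.ppm_axis.copy(),
            intensity=self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            meta=AcquisitionMeta(**asdict(self.meta)),
            intensity_imag=(None if intensity_imag is None and self.intensity_imag is None
                            else np.asarray(intensity_imag if intensity_imag is not None
                                            else self.intensity_imag, float).copy()),
        )


@dataclass
class RelaxationCurve:
    """Integrated amplitudes of one resonance versus recovery delay."""

    delays: np.ndarray
    amplitudes: np.ndarray
    resonance_label: str = ""
    microwaves_on: bool = True

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.delays.shape != self.amplitudes.shape or self.delays.ndim != 1:
            raise ValueError("delays and amplitudes must be equal-length 1-D vectors")
        if self.delays.size and self.delays[0] < 0:
            raise ValueError("delays must be >= 0")
        if self.delays.size > 1 and not np.all(np.diff(self.delays) > 0):
            raise ValueError("delays must be strictly increasing")


# ---------------------------------------------------------------------------
# Bruker TopSpin processed data
# ---------------------------------------------------------------------------

_PARAM_RE = re.compile(r"##\$?([A-Za-z_0-9]+)=\s*(.*)")


def _parse_jcamp_params(path: Path) -> dict[str, str]:
    params: dict[str, str] = {}
    for line in path.read_text(errors="replace").splitlines():
        m = _PARAM_RE.match(line)
        if m:
            params[m.group(1)] = m.group(2).strip()
    return params


def _find_procdir(path: Path) -> Path:
    """Accept either a dataset dir (containing pdata/<n>) or a procno dir."""
    path = Path(path)
    if (path / "procs").exists():
        return path
    pdata = path / "pdata"
    if pdata.is_dir():
        procnos = sorted(
            (d for d in pdata.iterdir() if d.is_dir() and (d / "procs").exists()),
            key=lambda d: (len(d.name), d.name),
        )
        if procnos:
            return procnos[0]
    raise SpectrumFormatError(f"no Bruker processed dataset (procs file) under {path}")


def read_bruker_processed(path: str | Path, meta: AcquisitionMeta | None = None) -> Spectrum1D:
    """Read a Bruker TopSpin processed 1D dataset.

    ``path`` may point at the dataset directory (``.../<expno>``) or directly
    at a ``pdata/<procno>`` directory.  The ppm axis is reconstructed from the
    ``OFFSET`` (ppm of the first point), ``SW_p`` (processed spectral width,
    Hz), ``SF`` (spectrometer frequency, MHz) and ``SI`` (number of points)
    entries of ``procs``::

        ppm[i] = OFFSET - i * (SW_p / SF) / SI,   i = 0 .. SI-1

    Both integer (``DTYPP == 0``, scaled by ``2**NC_proc``) and float64
    (``DTYPP == 2``) processed arrays are supported; ``1i`` is attached as the
    imaginary part when present.
    """
    procdir = _find_procdir(Path(path))
    params = _parse_jcamp_params(procdir / "procs")

    required = ("SI", "SW_p", "SF", "OFFSET")
    missing = [k for k in required if k not in params]
    if missing:
        raise SpectrumFormatError(
            f"procs in {procdir} is missing required field(s): {', '.join(missing)}")

    si = int(float(params["SI"]))
    sw_hz = float(params["SW_p"])
    sf_mhz = float(params["SF"])
    offset_ppm = float(params["OFFSET"])
    if si < 2 or sw_hz <= 0 or sf_mhz <= 0:
        raise SpectrumFormatError(f"non-physical procs parameters in {procdir}")

    byte_order = "<" if int(float(params.get("BYTORDP", "0"))) == 0 else ">"
    dtypp = int(float(params.get("DTYPP", "0")))
    nc_proc = int(float(params.get("NC_proc", "0")))

    def _read_array(fname: str) -> np.ndarray:
        raw = (procdir / fname).read_bytes()
        if dtypp == 2:
            data = np.frombuffer(raw, dtype=byte_order + "f8").astype(float)
        else:
            data = np.frombuffer(raw, dtype=byte_order + "i4").astype(float)
            data = data * (2.0 ** nc_proc)
        if data.size < si:
            raise SpectrumFormatError(
                f"{fname} in {procdir} holds {data.size} points, procs says SI={si}")
        return data[:si]

    if not (procdir / "1r").exists():
        raise SpectrumFormatError(f"missing real data file 1r in {procdir}")
    real = _read_array("1r")
    imag = _read_array("1i") if (procdir / "1i").exists() else None

    sw_ppm = sw_hz / sf_mhz
    ppm = offset_ppm - np.arange(si) * (sw_ppm / si)

    if meta is None:
        meta = AcquisitionMeta(spectrometer_freq_13C=sf_mhz, label=str(path))
    return Spectrum1D(ppm_axis=ppm, intensity=real, meta=meta, intensity_imag=imag)


# ---------------------------------------------------------------------------
# Internal two-column text format
# ---------------------------------------------------------------------------

_META_FIELDS = {
    "spectrometer_freq_13C": float,
    "mas_rate": float,
    "temperature": float,
    "n_scans": int,
    "microwaves_on": lambda s: s.strip().lower() in ("true", "1", "yes"),
    "relaxation_delay": float,
    "label": str,
}


def write_internal(spec: Spectrum1D, path: str | Path) -> None:
    """Write a spectrum as header lines (``# key: value``) + two/three columns.

    Floats are written with 17 significant digits, so the round trip through
    :func:`read_internal` is lossless to better than 1e-12 relative.
    """
    path = Path(path)
    lines = ["# etherdnp-spectrum v1"]
    for key in _META_FIELDS:
        lines.append(f"# {key}: {getattr(spec.meta, key)}")
    lines.append("# columns: ppm intensity" + (" intensity_imag" if spec.intensity_imag is not None else ""))
    cols = [spec.ppm_axis, spec.intensity]
    if spec.intensity_imag is not None:
        cols.append(spec.intensity_imag)
    for row in zip(*cols):
        lines.append(" ".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_internal(path: str | Path) -> Spectrum1D:
    """Read a spectrum written by :func:`write_internal`."""
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"no such file: {path}")
    meta_kwargs: dict = {}
    rows: list[tuple[float, ...]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                if key in _META_FIELDS:
                    meta_kwargs[key] = _META_FIELDS[key](val.strip())
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise SpectrumFormatError(f"malformed data line in {path!s}: {line!r}")
        rows.append(tuple(float(p) for p in parts))
    if not rows:
        raise SpectrumFormatError(f"no data rows in {path!s}")
    arr = np.array(rows, dtype=float)
    imag = arr[:, 2] if arr.shape[1] == 3 else None
    return Spectrum1D(ppm_axis=arr[:, 0], intensity=arr[:, 1],
                      meta=AcquisitionMeta(**meta_kwargs), intensity_imag=imag)


def write_curve(curve: RelaxationCurve, path: str | Path) -> None:
    """Write a relaxation curve as two-column text (delay_s, amplitude)."""
    lines = [
        "# etherdnp-relaxation v1",
        f"# resonance_label: {curve.resonance_label}",
        f"# microwaves_on: {curve.microwaves_on}",
        "# columns: delay_s amplitude",
    ]
    for d, a in zip(curve.delays, curve.amplitudes):
        lines.append(f"{d:.17g} {a:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> RelaxationCurve:
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"no such file: {path}")
    label, mw_on = "", True
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("resonance_label:"):
                label = body.split(":", 1)[1].strip()
            elif body.startswith("microwaves_on:"):
                mw_on = body.split(":", 1)[1].strip().lower() in ("true", "1", "yes")
            continue
        d, a = line.split()[:2]
        rows.append((float(d), float(a)))
    if not rows:
        raise SpectrumFormatError(f"no data rows in {path!s}")
    arr = np.array(rows)
    return RelaxationCurve(delays=arr[:, 0], amplitudes=arr[:, 1],
                           resonance_label=label, microwaves_on=mw_on)


def ppm_to_index(spec: Spectrum1D, ppm: float) -> int:
    """Index of the axis point nearest to ``ppm``.

    Ties (a value exactly midway between two grid points) break toward the
    lower index, i.e. the downfield point.  Values outside the axis range
    raise ``ValueError``.
    """
    axis = spec.ppm_axis
    if ppm > axis[0] or ppm < axis[-1]:
        raise ValueError(f"{ppm} ppm outside axis range [{axis[-1]}, {axis[0]}]")
    dist = np.abs(axis - ppm)
    # argmin returns the first minimum, which on a decreasing axis is the
    # lower index for exact midpoints.
    return int(np.argmin(dist))
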