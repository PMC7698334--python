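"""Spectrum containers, the ppm axis, and plain-text spectrum I/O.

In vivo single-voxel 1H-MRS data arrive as frequency-domain point lists
(here: the plain-text export of a clinical MRS package), together with the
acquisition geometry: spectral width in Hz, number of real points, the
spectrometer frequency and the chemical shift of the carrier (set on the
residual water signal).  :class:`PpmAxis` is the bijection between point
index and chemical shift; spectra are stored left-to-right in ppm, i.e.
index 0 is the highest chemical shift, following NMR display convention.

The default in vivo geometry is a 1200 Hz spectral width over 1024 real
points at 3 T (proton frequency ~123.25 MHz) with the carrier at 4.70 ppm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError, SpectrumFormatError

IDHMUT = "IDHmut"
IDHWT = "IDHwt"
UNKNOWN = "unknown"
LABELS = (IDHMUT, IDHWT, UNKNOWN)

#: Proton frequency in MHz at 3 T and the water carrier shift in ppm.
#: The acquisition protocol fixes only the field strength and "carrier on
#: water"; these standard values are defaults, not constants baked into math.
DEFAULT_SPECTROMETER_FREQ_MHZ = 123.25
DEFAULT_CARRIER_PPM = 4.70


@dataclass(frozen=True)
class PpmAxis:
    """Map between point index and chemical shift (ppm).

    Parameters
    ----------
    n_points
        Number of (real) data points.
    sweep_width_hz
        Spectral width in Hz.
    spectrometer_freq_mhz
        Proton resonance frequency in MHz; 1 ppm corresponds to
        ``spectrometer_freq_mhz`` Hz.
    carrier_ppm
        Chemical shift of the spectral center (the carrier).

    Notes
    -----
    ``ppm(i) = carrier_ppm + ((n_points - 1) / 2 - i) * spacing_ppm``, so
    chemical shift decreases strictly with index and the points straddle the
    carrier symmetrically.  The total span ``n_points * spacing_ppm`` equals
    ``sweep_width_hz / spectrometer_freq_mhz``.
    """

    n_points: int
    sweep_width_hz: float
    spectrometer_freq_mhz: float
    carrier_ppm: float

    def __post_init__(self) -> None:
        if int(self.n_points) != self.n_points or self.n_points <= 0:
            raise InvalidParameterError(f"n_points must be a positive integer, got {self.n_points}")
        for name in ("sweep_width_hz", "spectrometer_freq_mhz", "carrier_ppm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be positive and finite, got {v}")

    @property
    def spacing_ppm(self) -> float:
        """Chemical-shift step between adjacent points, in ppm."""
        return self.sweep_width_hz / (self.n_points * self.spectrometer_freq_mhz)

    @property
    def span_ppm(self) -> float:
        """Total spectral span in ppm (``sweep_width / spectrometer_freq``)."""
        return self.sweep_width_hz / self.spectrometer_freq_mhz

    @property
    def _center(self) -> float:
        return (self.n_points - 1) / 2.0

    def ppm(self, index):
        """Chemical shift at integer point ``index`` (scalar or array)."""
        idx = np.asarray(index, dtype=float)
        out = self.carrier_ppm + (self._center - idx) * self.spacing_ppm
        return float(out) if np.isscalar(index) or out.ndim == 0 else out

    def ppm_values(self) -> np.ndarray:
        """Chemical shift of every point, decreasing with index."""
        return self.ppm(np.arange(self.n_points))

    def index_of(self, ppm: float) -> int:
        """Index of the point nearest to ``ppm``.

        Raises
        ------
        InvalidParameterError
            If ``ppm`` falls outside the axis range.
        """
        raw = self._center + (self.carrier_ppm - ppm) / self.spacing_ppm
        idx = int(np.rint(raw))
        if idx < 0 or idx >= self.n_points:
            raise InvalidParameterError(
                f"{ppm} ppm lies outside the axis range "
                f"[{self.ppm(self.n_points - 1):.4f}, {self.ppm(0):.4f}] ppm"
            )
        return idx

    def window_indices(self, low_ppm: float, high_ppm: float) -> np.ndarray:
        """Indices of points whose shift lies in ``[low_ppm, high_ppm]``."""
        if low_ppm >= high_ppm:
            raise InvalidParameterError(f"empty ppm window [{low_ppm}, {high_ppm}]")
        p = self.ppm_values()
        return np.nonzero((p >= low_ppm) & (p <= high_ppm))[0]


def build_ppm_axis(
    n_points: int,
    sweep_width_hz: float,
    spectrometer_freq_mhz: float = DEFAULT_SPECTROMETER_FREQ_MHZ,
    carrier_ppm: float = DEFAULT_CARRIER_PPM,
) -> PpmAxis:
    """Construct a :class:`PpmAxis` from acquisition metadata."""
    return PpmAxis(n_points, sweep_width_hz, spectrometer_freq_mhz, carrier_ppm)


def default_invivo_axis() -> PpmAxis:
    """The default in vivo axis: 1024 points over 1200 Hz at 3 T."""
    return build_ppm_axis(1024, 1200.0)


@dataclass
class Spectrum:
    """One frequency-domain 1H-MR spectrum.

    ``intensities`` is the real (absorption) part in file order: index 0 is
    the highest chemical shift.  ``imag`` optionally carries the imaginary
    (dispersion) part, required for zero-order phase correction.
    """

    intensities: np.ndarray
    axis: PpmAxis
    imag: np.ndarray | None = None
    sample_id: str = ""
    label: str = UNKNOWN
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 1 or len(self.intensities) != self.axis.n_points:
            raise InvalidParameterError(
                f"expected {self.axis.n_points} intensities, got shape {self.intensities.shape}"
            )
        if self.imag is not None:
            self.imag = np.asarray(self.imag, dtype=np.float64)
            if self.imag.shape != self.intensities.shape:
                raise InvalidParameterError("imaginary part must match the real part in length")
        if self.label not in LABELS:
            raise InvalidParameterError(f"label must be one of {LABELS}, got {self.label!r}")

    def replace(self, **kwargs) -> "Spectrum":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Plain-text spectrum files
#
# Format: '#'-prefixed "key: value" header lines (n_points, sweep_width_hz,
# spectrometer_freq_mhz, carrier_ppm, sample_id, label, plus free extras),
# then one float per line (real-only) or two whitespace-separated floats
# (real imaginary), index 0 = highest ppm.
# ---------------------------------------------------------------------------

_AXIS_KEYS = ("n_points", "sweep_width_hz", "spectrometer_freq_mhz", "carrier_ppm")


def write_spectrum_txt(spectrum: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as a plain-text point list with a ``#`` header."""
    lines = [
        f"# n_points: {spectrum.axis.n_points}",
        f"# sweep_width_hz: {spectrum.axis.sweep_width_hz!r}",
        f"# spectrometer_freq_mhz: {spectrum.axis.spectrometer_freq_mhz!r}",
        f"# carrier_ppm: {spectrum.axis.carrier_ppm!r}",
        f"# sample_id: {spectrum.sample_id}",
        f"# label: {spectrum.label}",
    ]
    for key, value in spectrum.meta.items():
        if isinstance(value, (str, int, float)):
            lines.append(f"# {key}: {value}")
    if spectrum.imag is None:
        lines.extend(repr(float(v)) for v in spectrum.intensities)
    else:
        lines.extend(
            f"{float(re)!r} {float(im)!r}"
            for re, im in zip(spectrum.intensities, spectrum.imag)
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spectrum_txt(path: str | os.PathLike, axis: PpmAxis | None = None) -> Spectrum:
    """Read a plain-text spectrum file.

    If ``axis`` is omitted it is reconstructed from the header, which must
    then carry all four acquisition keys.  If ``axis`` is given, a header
    point count (when present) must agree with it.
    """
    header: dict[str, str] = {}
    real: list[float] = []
    imag: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    header[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) not in (1, 2):
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: expected 1 or 2 columns, found {len(parts)}"
                )
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}: line {lineno}: non-numeric value") from exc
            real.append(values[0])
            if len(values) == 2:
                imag.append(values[1])
    if imag and len(imag) != len(real):
        raise SpectrumFormatError(f"{path}: mixed one- and two-column data lines")

    if axis is None:
        missing = [k for k in _AXIS_KEYS if k not in header]
        if missing:
            raise SpectrumFormatError(
                f"{path}: no axis given and header lacks key(s): {', '.join(missing)}"
            )
        axis = PpmAxis(
            int(header["n_points"]),
            float(header["sweep_width_hz"]),
            float(header["spectrometer_freq_mhz"]),
            float(header["carrier_ppm"]),
        )
    elif "n_points" in header and int(header["n_points"]) != axis.n_points:
        raise SpectrumFormatError(
            f"{path}: header declares {header['n_points']} points, axis expects {axis.n_points}"
        )
    if len(real) != axis.n_points:
        raise SpectrumFormatError(
            f"{path}: expected {axis.n_points} data points, found {len(real)}"
        )
    meta = {
        k: v for k, v in header.items() if k not in _AXIS_KEYS + ("sample_id", "label")
    }
    return Spectrum(
        np.array(real),
        axis,
        imag=np.array(imag) if imag else None,
        sample_id=header.get("sample_id", ""),
        label=header.get("label", UNKNOWN),
        meta=meta,
    )


# Feature-matrix CSV I/O lives with the FeatureMatrix container; re-exported
# here because spectrum and matrix files form one I/O surface.
from .features import (  # noqa: E402  (re-export)
    FeatureMatrix,
    read_feature_matrix_csv,
    write_feature_matrix_csv,
)

__all__ = [
    "IDHMUT",
    "IDHWT",
    "UNKNOWN",
    "LABELS",
    "PpmAxis",
    "Spectrum",
    "build_ppm_axis",
    "default_invivo_axis",
    "read_spectrum_txt",
    "write_spectrum_txt",
    "FeatureMatrix",
    "read_feature_matrix_csv",
    "write_feature_matrix_csv",
]
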