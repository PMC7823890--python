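"""MS/MS spectrum container and MGF input/output.

The in-memory unit is :class:`FragmentSpectrum` — one spectrum per
LC-MS feature, as exported by feature-finding software (one MGF entry
per aligned feature, ``FEATURE_ID``/``SCANS`` in the title or scans
field).  Peaks are kept as parallel numpy arrays sorted by m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["FragmentSpectrum", "read_mgf", "write_mgf"]


@dataclass
class FragmentSpectrum:
    """One feature's MS/MS evidence.

    Attributes
    ----------
    feature_id:
        Stable identifier linking the spectrum to the quantification
        table.
    precursor_mz:
        Precursor ion m/z (> 0).
    charge:
        Precursor charge state (positive mode; 1 throughout).
    retention_time:
        Retention time in minutes (0 if unknown).
    mz, intensity:
        Peak arrays, sorted ascending by m/z, intensities >= 0.
    """

    feature_id: str
    precursor_mz: float
    charge: int = 1
    retention_time: float = 0.0
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    title: Optional[str] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @classmethod
    def from_peaks(
        cls,
        feature_id: str,
        precursor_mz: float,
        peaks: Iterable[Tuple[float, float]],
        **kwargs,
    ) -> "FragmentSpectrum":
        peaks = list(peaks)
        mz = [p[0] for p in peaks]
        inten = [p[1] for p in peaks]
        return cls(feature_id, precursor_mz, mz=np.array(mz), intensity=np.array(inten), **kwargs)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


def read_mgf(path: Union[str, Path]) -> List[FragmentSpectrum]:
    """Read an MGF file into a list of :class:`FragmentSpectrum`.

    The feature id is taken from ``FEATURE_ID``, else ``SCANS``, else
    the ``TITLE`` field, else a running index.
    """
    spectra: List[FragmentSpectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            fid = str(
                params.get("feature_id")
                or params.get("scans")
                or params.get("title")
                or i
            )
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 1
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else 0.0
            spectra.append(
                FragmentSpectrum(
                    feature_id=fid,
                    precursor_mz=precursor,
                    charge=charge,
                    retention_time=rt_min,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    title=params.get("title"),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[FragmentSpectrum], path: Union[str, Path]) -> None:
    """Write spectra to MGF (BEGIN IONS / PEPMASS / CHARGE / RTINSECONDS).

    Peak values are written with fixed precision so that identical
    inputs produce byte-identical files.
    """
    lines: List[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"FEATURE_ID={s.feature_id}")
        lines.append(f"TITLE={s.title if s.title is not None else s.feature_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.5f}")
        lines.append(f"CHARGE={s.charge}+")
        lines.append(f"RTINSECONDS={s.retention_time * 60.0:.3f}")
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.5f} {inten:.2f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))
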