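"""Peak lists and Mascot Generic Format (MGF) I/O.

MGF is the ingest and exchange format for MS/MS peak lists here; parsing
and writing go through :mod:`pyteomics.mgf`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = ["Spectrum", "read_mgf", "write_mgf"]


@dataclass
class Spectrum:
    """One MS/MS scan: precursor m/z + charge and a peak list.

    Peaks are kept as parallel arrays sorted by m/z.  ``charge`` may be
    None when the instrument did not assign one.
    """

    title: str
    precursor_mz: float
    charge: int | None
    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self):
        return len(self.mz)

    def neutral_mass(self, charge: int | None = None) -> float:
        from .mods import neutral_mass_from_mz

        z = charge if charge is not None else self.charge
        if z is None:
            raise ValueError(f"spectrum {self.title!r} has no charge assignment")
        return neutral_mass_from_mz(self.precursor_mz, z)


def read_mgf(source) -> list[Spectrum]:
    """Read all BEGIN IONS/END IONS blocks from an MGF file or stream.

    Blocks without a PEPMASS line are skipped with a logged warning.
    CHARGE values like ``2+`` parse to integer 2.
    """
    spectra = []
    with _mgf.MGF(source) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                logger.warning("skipping MGF block %d (%s): no PEPMASS",
                               i, params.get("title", "untitled"))
                continue
            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else None
            spectra.append(
                Spectrum(
                    title=params.get("title", f"scan_{i}"),
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


def write_mgf(spectra, destination) -> None:
    """Write spectra as MGF; round-trips titles, precursors, charges, peaks."""
    entries = []
    for s in spectra:
        params = {"title": s.title, "pepmass": s.precursor_mz}
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    _mgf.write(entries, destination)
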