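"""Theoretical fragment-ion ladders, annotation, and site localization.

Collision-induced dissociation of a protonated peptide yields N-terminal
b ions (and a ions, b − CO) and C-terminal y ions.  A covalent modification
at residue p shifts exactly the b_i/a_i with i >= p and the y_j with
j > n − p; the complementary series is untouched.  This asymmetry is what
makes a heavy lysine tag such as Uniblue A useful: every N-terminal ion
downstream of the labeled lysine moves by the full tag mass, so the label
position can be read off the ladder.

The charge heuristic reflects the tag's sulfonate group: a derivatized
lysine no longer protonates, so each label removes one charge from the
electrospray charge-state estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mods import (
    CO_MONO,
    MONO_RESIDUE_MASS,
    NH3_MONO,
    WATER_MONO,
    ModificationSpec,
    Modform,
    mz_from_mass,
)
from .spectra import Spectrum

__all__ = [
    "FragmentIon",
    "Annotation",
    "PairedComparison",
    "fragment_ladder",
    "predict_charge",
    "annotate_spectrum",
    "localize_site",
    "compare_paired_spectra",
]

_LOSS_MASS = {None: 0.0, "NH3": NH3_MONO, "H2O": WATER_MONO}
_LOSS_ORDER = (None, "NH3", "H2O")


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'a' | 'b' | 'y'
    index: int  # 1..n-1
    charge: int
    loss: str | None
    mz: float
    carries_modification: bool

    def ion_label(self) -> str:
        loss = f"-{self.loss}" if self.loss else ""
        z = f"^{self.charge}" if self.charge > 1 else ""
        return f"{self.series}{self.index}{loss}{z}"


@dataclass(frozen=True)
class Annotation:
    peak_index: int
    ion: FragmentIon
    mass_error: float  # observed - theoretical, Da


def fragment_ladder(
    modform: Modform | str,
    series: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
    losses: Iterable[str] = (),
) -> list[FragmentIon]:
    """All theoretical a/b/y fragment ions of a modform.

    Ion m/z follow the standard CID definitions: the b_i neutral fragment is
    the sum of the first i residue masses plus the modification deltas on
    positions <= i; y_j adds water to the last j residues plus deltas on
    positions > n − j; a_i = b_i − CO.  Neutral losses subtract NH3/H2O.
    Multiply charged ions are protonated forms of the same neutral fragment.
    """
    if isinstance(modform, str):
        modform = Modform(modform)
    seq = modform.sequence
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    series = sorted(set(series))
    unknown = set(series) - {"a", "b", "y"}
    if unknown:
        raise ValueError(f"unsupported ion series {sorted(unknown)}")
    losses = [l for l in _LOSS_ORDER if l in set(losses)]
    loss_list = [None] + losses

    residue = np.array([MONO_RESIDUE_MASS[aa] for aa in seq])
    delta = np.zeros(n)
    for pos, spec in modform.sites.items():
        delta[pos - 1] = spec.mono_delta
    cum_res = np.cumsum(residue)
    cum_delta = np.cumsum(delta)
    total_res, total_delta = cum_res[-1], cum_delta[-1]

    ions = []
    for ser in series:
        for idx in range(1, n):
            if ser in ("a", "b"):
                neutral = cum_res[idx - 1] + cum_delta[idx - 1]
                if ser == "a":
                    neutral -= CO_MONO
                carries = cum_delta[idx - 1] > 0
            else:
                neutral = (
                    (total_res - cum_res[n - idx - 1])
                    + (total_delta - cum_delta[n - idx - 1])
                    + WATER_MONO
                )
                carries = (total_delta - cum_delta[n - idx - 1]) > 0
            for loss in loss_list:
                frag = neutral - _LOSS_MASS[loss]
                for z in range(1, max_charge + 1):
                    ions.append(
                        FragmentIon(
                            series=ser,
                            index=idx,
                            charge=z,
                            loss=loss,
                            mz=mz_from_mass(frag, z),
                            carries_modification=bool(carries),
                        )
                    )
    return ions


def predict_charge(modform: Modform | str) -> int:
    """Electrospray charge-state estimate: one proton for the N-terminus
    plus one per arginine and per *unmodified* lysine (a derivatized lysine
    has lost its protonation site), floored at 1."""
    if isinstance(modform, str):
        modform = Modform(modform)
    seq = modform.sequence
    n_r = seq.count("R")
    n_k_free = sum(
        1 for pos, aa in enumerate(seq, start=1)
        if aa == "K" and pos not in modform.sites
    )
    return max(1, 1 + n_r + n_k_free)


def _match_counts(ions: Sequence[FragmentIon], spectrum: Spectrum, tol: float):
    """Nearest-peak match per theoretical ion; returns (matched mask, peak idx,
    error)."""
    theo = np.array([ion.mz for ion in ions])
    if len(spectrum) == 0 or len(theo) == 0:
        return (
            np.zeros(len(theo), dtype=bool),
            np.zeros(len(theo), dtype=int),
            np.zeros(len(theo)),
        )
    pos = np.searchsorted(spectrum.mz, theo)
    left = np.clip(pos - 1, 0, len(spectrum) - 1)
    right = np.clip(pos, 0, len(spectrum) - 1)
    err_left = spectrum.mz[left] - theo
    err_right = spectrum.mz[right] - theo
    take_right = np.abs(err_right) < np.abs(err_left)
    peak_idx = np.where(take_right, right, left)
    error = np.where(take_right, err_right, err_left)
    return np.abs(error) <= tol, peak_idx, error


def annotate_spectrum(
    spectrum: Spectrum,
    modform: Modform | str,
    fragment_tolerance: float = 0.8,
    series: Iterable[str] = ("b", "y"),
    max_charge: int | None = None,
    losses: Iterable[str] = (),
) -> list[Annotation]:
    """Match each theoretical ion to its nearest peak within tolerance.

    One peak may satisfy several theoretical ions.  ``max_charge`` defaults
    to one below the precursor charge (floored at 1) when the spectrum has
    one, else 1.  Annotations are sorted by peak m/z.
    """
    if fragment_tolerance <= 0:
        raise ValueError("fragment_tolerance must be > 0")
    if max_charge is None:
        max_charge = max(1, (spectrum.charge or 2) - 1)
    ions = fragment_ladder(modform, series=series, max_charge=max_charge,
                           losses=losses)
    matched, peak_idx, error = _match_counts(ions, spectrum, fragment_tolerance)
    annotations = [
        Annotation(peak_index=int(peak_idx[i]), ion=ions[i],
                   mass_error=float(error[i]))
        for i in range(len(ions))
        if matched[i]
    ]
    annotations.sort(key=lambda a: (spectrum.mz[a.peak_index], a.ion.ion_label()))
    return annotations


def localize_site(
    spectrum: Spectrum,
    sequence: str,
    modification: ModificationSpec,
    tolerance: float = 0.8,
    series: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
    losses: Iterable[str] = (),
):
    """Locate a single modification on ``sequence`` from its MS/MS spectrum.

    Each eligible residue is scored by the number of matched site-determining
    ions (fragments whose m/z differs between candidate placements).  Returns
    ``(best 1-based position, {position: score}, ambiguous)``; ties resolve
    to the lowest position with ``ambiguous=True``.
    """
    candidates = [
        pos for pos, aa in enumerate(sequence, start=1)
        if aa in modification.target_residues
    ]
    if not candidates:
        raise ValueError(
            f"no residue in {sequence!r} is eligible for {modification.name}"
        )
    ladders = {
        pos: fragment_ladder(
            Modform(sequence, {pos: modification}),
            series=series, max_charge=max_charge, losses=losses,
        )
        for pos in candidates
    }
    # an ion coordinate is site-determining if its m/z varies across candidates
    ion_keys = [(i.series, i.index, i.charge, i.loss) for i in ladders[candidates[0]]]
    mz_matrix = np.array([[ion.mz for ion in ladders[p]] for p in candidates])
    determining = (mz_matrix.max(axis=0) - mz_matrix.min(axis=0)) > 1e-9

    scores = {}
    for row, pos in enumerate(candidates):
        ions = [ion for ion, det in zip(ladders[pos], determining) if det]
        matched, _, _ = _match_counts(ions, spectrum, tolerance)
        scores[pos] = int(matched.sum())
    best_score = max(scores.values())
    winners = [p for p in candidates if scores[p] == best_score]
    return winners[0], scores, len(winners) > 1


@dataclass
class PairedComparison:
    """Outcome of comparing the spectra of a labeled and an unlabeled form
    of the same peptide sequence."""

    table: pd.DataFrame  # per series/index: theoretical m/z pair + match flags
    matched_counts: dict  # series -> (n matched modified, n matched native)
    shifted_series: dict  # series -> True if any index moved by > tolerance


def compare_paired_spectra(
    spectrum_modified: Spectrum,
    modform_modified: Modform,
    spectrum_native: Spectrum,
    modform_native: Modform,
    tolerance: float = 0.8,
    series: Iterable[str] = ("a", "b", "y"),
) -> PairedComparison:
    """Per-series comparison of a modified/native spectrum pair (mirror-plot
    ready).  Both modforms must share the same plain sequence.

    For each singly charged fragment the table reports the theoretical m/z of
    both forms, their difference, and whether each spectrum shows the peak.
    A lysine tag at position p shifts every a/b index >= p by the tag mass
    and leaves the y series untouched.
    """
    if modform_modified.sequence != modform_native.sequence:
        raise ValueError(
            "paired comparison requires identical plain sequences, got "
            f"{modform_modified.sequence!r} vs {modform_native.sequence!r}"
        )
    rows = []
    matched_counts = {}
    shifted = {}
    for ser in sorted(set(series)):
        ions_mod = fragment_ladder(modform_modified, series=(ser,), max_charge=1)
        ions_nat = fragment_ladder(modform_native, series=(ser,), max_charge=1)
        m_mod, _, _ = _match_counts(ions_mod, spectrum_modified, tolerance)
        m_nat, _, _ = _match_counts(ions_nat, spectrum_native, tolerance)
        matched_counts[ser] = (int(m_mod.sum()), int(m_nat.sum()))
        deltas = []
        for im, inat, hm, hn in zip(ions_mod, ions_nat, m_mod, m_nat):
            d = im.mz - inat.mz
            deltas.append(d)
            rows.append(
                {
                    "series": ser,
                    "index": im.index,
                    "mz_modified": im.mz,
                    "mz_native": inat.mz,
                    "delta_mz": d,
                    "matched_modified": bool(hm),
                    "matched_native": bool(hn),
                }
            )
        shifted[ser] = bool(max(abs(d) for d in deltas) > tolerance) if deltas else False
    table = pd.DataFrame(rows).sort_values(["series", "index"]).reset_index(drop=True)
    return PairedComparison(table=table, matched_counts=matched_counts,
                            shifted_series=shifted)
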