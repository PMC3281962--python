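"""Peptide-spectrum matching with a Poisson-tail score and target-decoy FDR.

Scoring model: with n peaks in a spectrum spanning an m/z range R, a single
theoretical ion falls within the fragment tolerance t of some peak by chance
with probability ~ n·2t/R, so the number of random matches among N
theoretical ions is approximately Poisson with rate λ = n·2t·N/R.  The PSM
p-value is the upper tail P(X ≥ k) at the observed match count k, and the
E-value multiplies by the number of candidates scored for the spectrum.
Confidence is then calibrated empirically against reversed-sequence decoys:
PSMs are ranked by E-value and each receives the q-value
min over thresholds at or below it of  #decoy / max(1, #target).

This native scorer + direct target-decoy q-values stand in for an external
search engine and post-search mixture-model validation; the modification
handling (heavy lysine tag, cleavage blocking) is independent of the choice
of scorer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import poisson

from .database import PeptideIndex
from .fragments import _match_counts, fragment_ladder
from .mods import (
    CARBAMIDOMETHYL_C,
    DEAMIDATION_NQ,
    UNIBLUE_A,
    Modform,
    neutral_mass_from_mz,
)
from .spectra import Spectrum, read_mgf, write_mgf  # re-exported  # noqa: F401

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "PSM",
    "score_psm",
    "search_dataset",
    "compute_fdr",
    "psms_to_table",
    "read_mgf",
    "write_mgf",
]


@dataclass(frozen=True)
class SearchParams:
    """Search configuration (defaults follow ion-trap CID practice:
    2.0 Da precursor / 0.8 Da fragment tolerances, 2 missed cleavages,
    fixed carbamidomethyl C, variable deamidation N/Q + Uniblue A K,
    minimum peptide length 5)."""

    precursor_tolerance: float = 2.0
    fragment_tolerance: float = 0.8
    max_missed: int = 2
    fixed: tuple = (CARBAMIDOMETHYL_C,)
    variable: tuple = (DEAMIDATION_NQ, UNIBLUE_A)
    max_variable: int = 3
    min_peptide_length: int = 5
    series: tuple = ("b", "y")
    losses: tuple = ()
    fallback_charges: tuple = (2, 3)
    e_value_cap: float = 1e6

    def __post_init__(self):
        if self.precursor_tolerance <= 0 or self.fragment_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")


@dataclass
class PSM:
    """A scored peptide-spectrum match."""

    spectrum_id: str
    modform: Modform
    protein_id: str | None
    is_decoy: bool
    k: int  # matched theoretical ions
    N: int  # theoretical ions
    p_value: float
    e_value: float
    n_candidates: int
    charge: int | None = None
    q_value: float | None = None
    rank: int | None = None


def score_psm(
    spectrum: Spectrum,
    modform: Modform | str,
    params: SearchParams = SearchParams(),
    max_fragment_charge: int | None = None,
):
    """Score one spectrum against one modform; returns ``(k, N, p_value)``.

    The random-match rate λ uses the spectrum's own peak-m/z span as the
    scan range.  A degenerate range (max <= min) is rejected.
    """
    if len(spectrum) == 0:
        raise ValueError("cannot score an empty spectrum")
    scan_min, scan_max = float(spectrum.mz.min()), float(spectrum.mz.max())
    if scan_max <= scan_min:
        raise ValueError(
            f"degenerate scan range [{scan_min}, {scan_max}] in {spectrum.title!r}"
        )
    if max_fragment_charge is None:
        max_fragment_charge = max(1, (spectrum.charge or 2) - 1)
    ions = fragment_ladder(
        modform,
        series=params.series,
        max_charge=max_fragment_charge,
        losses=params.losses,
    )
    matched, _, _ = _match_counts(ions, spectrum, params.fragment_tolerance)
    k = int(matched.sum())
    N = len(ions)
    lam = (
        len(spectrum)
        * 2.0
        * params.fragment_tolerance
        * N
        / (scan_max - scan_min)
    )
    p = 1.0 if k == 0 else float(poisson.sf(k - 1, lam))
    # guard against exact-zero underflow so downstream E-values stay ordered
    p = max(p, 5e-324)
    return k, N, p


def search_dataset(
    spectra: Sequence[Spectrum],
    index: PeptideIndex,
    params: SearchParams = SearchParams(),
) -> list[PSM]:
    """Search spectra against a peptide index; best PSM per spectrum, ranked.

    Candidates come from the precursor window (± precursor tolerance on the
    neutral mass, charge-aware; spectra without a charge try the fallback
    charges).  Peptides shorter than the minimum length and candidates above
    the missed-cleavage limit are excluded before scoring.  E-value =
    p-value × number of candidates scored; ties break on higher match count,
    then lexicographic modform.  Spectra with no candidates yield no PSM.
    """
    psms = []
    for spectrum in spectra:
        charges = [spectrum.charge] if spectrum.charge else list(params.fallback_charges)
        candidates = {}
        for z in charges:
            neutral = neutral_mass_from_mz(spectrum.precursor_mz, z)
            for entry in index.query_window(neutral, params.precursor_tolerance):
                if len(entry.modform.sequence) < params.min_peptide_length:
                    continue
                if entry.missed_cleavages > params.max_missed:
                    continue
                candidates.setdefault(
                    entry.modform.key() + (entry.protein_id,), (entry, z)
                )
        if not candidates:
            continue
        n_cand = len(candidates)
        best = None
        for entry, z in candidates.values():
            k, N, p = score_psm(
                spectrum, entry.modform, params,
                max_fragment_charge=max(1, z - 1),
            )
            # ties: higher match count, then fewer modification sites
            # (parsimony: at trap resolution a spurious +0.984 Da deamidation
            # on a multiply charged precursor can tie the unmodified form),
            # then lexicographic modform for determinism
            sort_key = (
                (p, -k, len(entry.modform.sites))
                + entry.modform.key()
                + (entry.protein_id,)
            )
            if best is None or sort_key < best[0]:
                best = (sort_key, entry, z, k, N, p)
        _, entry, z, k, N, p = best
        e_value = min(p * n_cand, params.e_value_cap)
        psms.append(
            PSM(
                spectrum_id=spectrum.title,
                modform=entry.modform,
                protein_id=entry.protein_id,
                is_decoy=entry.is_decoy,
                k=k,
                N=N,
                p_value=p,
                e_value=e_value,
                n_candidates=n_cand,
                charge=z,
            )
        )
    psms.sort(key=_psm_order)
    for rank, psm in enumerate(psms, start=1):
        psm.rank = rank
    return psms


def _psm_order(psm: PSM):
    return (
        (psm.e_value, -psm.k, len(psm.modform.sites))
        + psm.modform.key()
        + (psm.protein_id or "",)
    )


def compute_fdr(psms: Sequence[PSM]) -> list[PSM]:
    """Assign target-decoy q-values.

    PSMs are sorted by ascending E-value; at each threshold
    FDR = #decoy / max(1, #target) (clamped to 1), and the q-value is the
    running minimum of the FDR from the bottom of the list up, so q-values
    are non-decreasing with rank.  An all-decoy input gets q = 1 throughout.
    """
    ordered = sorted(psms, key=_psm_order)
    n_decoy = 0
    n_target = 0
    fdrs = []
    for psm in ordered:
        if psm.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(min(1.0, n_decoy / max(1, n_target)))
    out = []
    qs = [0.0] * len(ordered)
    running = float("inf")
    for i in range(len(ordered) - 1, -1, -1):
        running = min(running, fdrs[i])
        qs[i] = running
    for rank, (psm, q) in enumerate(zip(ordered, qs), start=1):
        out.append(replace_psm(psm, q_value=q, rank=rank))
    return out


def replace_psm(psm: PSM, **kwargs) -> PSM:
    from dataclasses import replace as _replace

    return _replace(psm, **kwargs)


def psms_to_table(psms: Sequence[PSM]):
    """PSM list as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "spectrum": [p.spectrum_id for p in psms],
            "sequence": [p.modform.sequence for p in psms],
            "modifications": [p.modform.mods_string() for p in psms],
            "modifications_psimod": [p.modform.mods_string(psimod=True) for p in psms],
            "protein": [p.protein_id for p in psms],
            "charge": [p.charge for p in psms],
            "k": [p.k for p in psms],
            "N": [p.N for p in psms],
            "p_value": [p.p_value for p in psms],
            "e_value": [p.e_value for p in psms],
            "decoy": [p.is_decoy for p in psms],
            "q_value": [p.q_value for p in psms],
        }
    )
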