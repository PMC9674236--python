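"""Targeted MS1 verification: isotope envelopes, idotp, detection calls.

A target ion's theoretical isotope envelope (relative intensities of the
M, M+1, ... M+4 isotopologues) is computed by convolving the natural
isotope distributions of its elemental composition.  An observed envelope
is accepted when its normalized dot product against the theoretical one
(idotp) reaches the threshold and, when a retention time is supplied, the
ion elutes inside the expected window; accepted ions are quantified as the
sum of the five isotope intensities, otherwise the abundance is zero
(n.d.).  Observed envelopes are consumed from plain TSV, not raw spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as pt_mass

IDOTP_THRESHOLD = 0.88
RT_WINDOW = (89.0, 91.0)
N_ISOTOPES = 5

#: Natural isotope abundances, indexed by neutron offset from the most
#: abundant isotope's nominal mass.  Pinned so envelopes are
#: bit-reproducible across versions of downstream libraries.
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: Modification composition deltas.  C-terminal amidation replaces the
#: carboxyl OH with NH2 (net -O +N +H); oxidation adds one oxygen.
MODIFICATION_DELTAS: dict[str, dict[str, int]] = {
    "amidated_C_term": {"O": -1, "N": 1, "H": 1},
    "oxidation": {"O": 1},
    "acetyl_N_term": {"C": 2, "H": 2, "O": 1},
}


class MS1Error(ValueError):
    pass


@dataclass(frozen=True)
class TargetIon:
    sequence: str
    modifications: frozenset[str] = frozenset()
    charge: int = 2

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise MS1Error("charge must be >= 1")
        unknown = set(self.modifications) - set(MODIFICATION_DELTAS)
        if unknown:
            raise MS1Error(f"unknown modifications {sorted(unknown)}")


@dataclass
class IsotopeEnvelope:
    intensities: np.ndarray
    mz: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if (self.intensities < 0).any():
            raise MS1Error("negative envelope intensity")
        if self.normalized:
            s = self.intensities.sum()
            if not np.isclose(s, 1.0, atol=1e-9):
                raise MS1Error(f"normalized envelope sums to {s}, not 1")

    def normalize(self) -> "IsotopeEnvelope":
        s = self.intensities.sum()
        if s == 0:
            raise MS1Error("cannot normalize an all-zero envelope")
        return IsotopeEnvelope(self.intensities / s, self.mz, normalized=True)

    def __len__(self) -> int:
        return len(self.intensities)


def elemental_composition(ion: TargetIon) -> dict[str, int]:
    """CHNOS counts of the (neutral) modified peptide: residue formulas plus
    one water, plus modification deltas."""
    if not ion.sequence:
        raise MS1Error("empty sequence")
    try:
        comp = pt_mass.Composition(sequence=ion.sequence)
    except Exception as exc:  # pyteomics raises its own error type
        raise MS1Error(f"cannot compute composition of {ion.sequence!r}: {exc}") from exc
    counts = dict(comp)
    for mod in ion.modifications:
        for el, delta in MODIFICATION_DELTAS[mod].items():
            counts[el] = counts.get(el, 0) + delta
    if any(v < 0 for v in counts.values()):
        raise MS1Error(f"negative element count for {ion.sequence!r}")
    return {el: int(counts[el]) for el in sorted(counts) if counts[el]}


def _power_convolve(dist: np.ndarray, n: int, size: int) -> np.ndarray:
    """dist convolved with itself n times, truncated to ``size`` terms.

    Truncation during accumulation is exact for the retained prefix because
    term k of a convolution only involves terms <= k of the factors.
    """
    result = np.zeros(size)
    result[0] = 1.0
    base = np.zeros(size)
    base[: min(size, len(dist))] = dist[:size]
    while n:
        if n & 1:
            result = np.convolve(result, base)[:size]
        base = np.convolve(base, base)[:size]
        n >>= 1
    return result


def theoretical_envelope(composition: dict[str, int], n_isotopes: int = N_ISOTOPES) -> IsotopeEnvelope:
    """Isotopologue probabilities by elementwise convolution, truncated to
    ``n_isotopes`` and renormalized."""
    if any(v < 0 for v in composition.values()):
        raise MS1Error("negative element count")
    env = np.zeros(n_isotopes)
    env[0] = 1.0
    for el, count in sorted(composition.items()):
        if count == 0:
            continue
        if el not in ISOTOPE_ABUNDANCES:
            raise MS1Error(f"no isotope table for element {el!r}")
        dist = np.asarray(ISOTOPE_ABUNDANCES[el], dtype=float)
        env = np.convolve(env, _power_convolve(dist, count, n_isotopes))[:n_isotopes]
    return IsotopeEnvelope(env / env.sum(), normalized=True)


def idotp(observed: IsotopeEnvelope, theoretical: IsotopeEnvelope) -> float:
    """Normalized dot product <o, t> / (||o|| ||t||) in [0, 1]."""
    o = np.asarray(observed.intensities, dtype=float)
    t = np.asarray(theoretical.intensities, dtype=float)
    if len(o) != len(t):
        raise MS1Error(f"envelope length mismatch: {len(o)} vs {len(t)}")
    if not t.any():
        raise MS1Error("theoretical envelope is all zero")
    if not o.any():
        return 0.0
    return float(np.dot(o, t) / (np.linalg.norm(o) * np.linalg.norm(t)))


def total_abundance(observed: IsotopeEnvelope) -> float:
    """Sum of the M..M+4 intensities."""
    if len(observed) != N_ISOTOPES:
        raise MS1Error(f"expected {N_ISOTOPES} isotopes, got {len(observed)}")
    return float(observed.intensities.sum())


@dataclass(frozen=True)
class DetectionResult:
    detected: bool
    idotp: float
    abundance: float

    @property
    def log2_abundance(self) -> float:
        return float(np.log2(self.abundance)) if self.abundance > 0 else float("-inf")


def call_detection(observed: IsotopeEnvelope, theoretical: IsotopeEnvelope,
                   idotp_threshold: float = IDOTP_THRESHOLD,
                   rt_observed: float | None = None,
                   rt_window: tuple[float, float] = RT_WINDOW) -> DetectionResult:
    """Accept the ion iff idotp >= threshold and (when an RT is given) the
    elution time lies inside the window, both inclusive; otherwise the
    abundance is set to zero (n.d.)."""
    score = idotp(observed, theoretical)
    ok = score >= idotp_threshold
    if ok and rt_observed is not None:
        ok = rt_window[0] <= rt_observed <= rt_window[1]
    return DetectionResult(ok, score, total_abundance(observed) if ok else 0.0)


# ---------------------------------------------------------------------------
# TSV-level workflow


def read_targets_tsv(path: str | Path) -> list[TargetIon]:
    df = pd.read_csv(path, sep="\t")
    targets = []
    for _, row in df.iterrows():
        mods = frozenset(str(row.get("modifications", "")).split(";")) - {"", "nan"}
        targets.append(TargetIon(row["sequence"], mods, int(row.get("charge", 2))))
    return targets


def run_ms1(targets: list[TargetIon], envelopes: pd.DataFrame,
            idotp_threshold: float = IDOTP_THRESHOLD,
            rt_window: tuple[float, float] = RT_WINDOW) -> pd.DataFrame:
    """Score one observed envelope per (target sequence, sample) row.

    ``envelopes`` columns: sequence, sample, m0..m4, optional rt.
    """
    theo = {t.sequence: theoretical_envelope(elemental_composition(t)) for t in targets}
    rows = []
    for _, row in envelopes.iterrows():
        seq = row["sequence"]
        if seq not in theo:
            continue
        obs = IsotopeEnvelope(np.array([row[f"m{i}"] for i in range(N_ISOTOPES)], dtype=float))
        rt = float(row["rt"]) if "rt" in envelopes.columns and pd.notna(row.get("rt")) else None
        res = call_detection(obs, theo[seq], idotp_threshold, rt, rt_window)
        rows.append({
            "sequence": seq, "sample": row["sample"], "idotp": res.idotp,
            "detected": res.detected, "abundance": res.abundance,
            "log2_abundance": res.log2_abundance if res.detected else 0.0,
        })
    return pd.DataFrame(rows)
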