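"""Feature registry: the 23 per-lead ECG features and the 276-dim lead-major layout.

Every stage of the pipeline (extraction, adjustment, partitioning,
classification, explanation) addresses features through this registry, so the
name <-> index map is defined exactly once.  Columns in feature tables are
named ``<lead>_<feature>`` (e.g. ``aVR_q_amplitude``).
"""

from __future__ import annotations

LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

# (name, unit, ECG component) in fixed registry order.  Depolarization:
# Q/R/S amplitudes, QRS durations (total, onset->R peak a.k.a. intrinsicoid
# deflection, R peak->offset), R up/down slopes, fragmentation, energy and
# signed area.  Repolarization: ST segment, T wave, TP segment descriptors.
FEATURES: tuple[tuple[str, str, str], ...] = (
    ("q_amplitude", "mV", "Q"),
    ("r_amplitude", "mV", "QRS"),
    ("s_amplitude", "mV", "QRS"),
    ("qrs_duration", "s", "QRS"),
    ("qrs_nonterminal_duration", "s", "QRS"),
    ("qrs_terminal_duration", "s", "QRS"),
    ("r_upstroke_slope", "mV/s", "QRS"),
    ("r_downstroke_slope", "mV/s", "QRS"),
    ("qrs_fragmentation", "count", "QRS"),
    ("qrs_energy", "mV^2*s", "QRS"),
    ("qrs_auc", "mV*s", "QRS"),
    ("st_duration", "s", "ST"),
    ("st_deviation", "mV", "ST"),
    ("st_slope", "mV/s", "ST"),
    ("t_amplitude", "mV", "T"),
    ("t_duration", "s", "T"),
    ("t_inversion", "sign", "T"),
    ("t_upslope", "mV/s", "T"),
    ("t_downslope", "mV/s", "T"),
    ("t_energy", "mV^2*s", "T"),
    ("t_auc", "mV*s", "T"),
    ("tp_slope", "mV/s", "TP"),
    ("tp_duration", "s", "TP"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(name for name, _, _ in FEATURES)
N_FEATURES: int = len(FEATURES)          # 23
N_LEADS: int = len(LEADS)                # 12
VECTOR_LENGTH: int = N_FEATURES * N_LEADS  # 276

COMPONENTS: tuple[str, ...] = ("Q", "QRS", "ST", "T", "TP")
COMPONENT_OF: dict[str, str] = {name: comp for name, _, comp in FEATURES}
UNIT_OF: dict[str, str] = {name: unit for name, unit, _ in FEATURES}

#: 276 column names in lead-major order: all 23 features of lead I, then II, ...
VECTOR_COLUMNS: tuple[str, ...] = tuple(
    f"{lead}_{feat}" for lead in LEADS for feat in FEATURE_NAMES
)

_INDEX_OF = {name: i for i, name in enumerate(VECTOR_COLUMNS)}


def feature_index(lead: str, feature: str) -> int:
    """Position of ``<lead>_<feature>`` in the 276-long vector."""
    try:
        return _INDEX_OF[f"{lead}_{feature}"]
    except KeyError:
        raise KeyError(f"unknown lead/feature pair: {lead}_{feature}") from None


def column_lead(column: str) -> str:
    lead, _, _ = column.partition("_")
    return lead


def column_feature(column: str) -> str:
    _, _, feat = column.partition("_")
    return feat
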