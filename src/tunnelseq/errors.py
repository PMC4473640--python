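"""Exception hierarchy for tunnelseq."""


class TunnelSeqError(Exception):
    """Base class for all tunnelseq errors."""


class AlphabetError(TunnelSeqError, ValueError):
    """Sequence symbol or alphabet-kind mismatch."""


class SchemaError(TunnelSeqError, ValueError):
    """Unsupported or corrupt serialized container."""


class SingularOverlapError(TunnelSeqError):
    """Overlap matrix is not usable (not SPD or ill-conditioned)."""


class SingularEnergyError(TunnelSeqError):
    """Effective Hamiltonian requested at (or too close to) a pole."""


class QuadratureError(TunnelSeqError):
    """Adaptive energy integration failed to reach the requested tolerance."""


class CalibrationError(TunnelSeqError):
    """Invalid calibration configuration or under-populated PDF class."""
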