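"""Package-specific exceptions."""


class SimulationError(RuntimeError):
    """The 1-D vessel solver diverged or was given an inconsistent setup."""


class BalanceNotBracketedError(ValueError):
    """The velocity-difference curve does not change sign on the Pe sweep grid.

    Happens physically when the balance external pressure would be negative,
    e.g. ICP = 0 with a positive intraorbital pressure.
    """


class CalibrationError(ValueError):
    """BFF-to-ICP calibration is impossible (degenerate regressor)."""
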