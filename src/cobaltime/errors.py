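"""Exception types shared across the package."""


class CobaltimeError(ValueError):
    """Base class for all validation and domain errors raised by cobaltime."""


class PlanValidationError(CobaltimeError):
    """A plan, aperture, or record file violates the documented schema.

    Messages name the offending field and index so that hand-edited JSON
    can be fixed quickly.
    """


class DomainError(CobaltimeError):
    """Inputs are well-formed but physically or mathematically inadmissible,

    e.g. a beam parked outside its head's reachable gantry arc, a treatment
    date before the source calibration date, or a degenerate regression
    design.
    """
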