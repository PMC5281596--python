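"""Exception hierarchy for the vmmn package."""


class VmmnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VmmnError):
    """A parameter set violates its invariants (e.g. non-integral deviant count)."""


class ConstraintError(VmmnError):
    """A combinatorial constraint cannot be satisfied (e.g. task-event placement)."""


class PairingError(VmmnError):
    """Difference-wave operands describe physically different stimuli."""


class DesignError(VmmnError):
    """A statistical design is unbalanced or otherwise unusable."""


class LabelError(VmmnError, KeyError):
    """A channel or factor label is unknown."""


class EmptyConditionError(VmmnError):
    """No retained epochs match the requested condition."""
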