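"""Exception hierarchy."""


class IgxError(Exception):
    """Base class for all igxchange errors."""


class AlignmentFloorError(IgxError):
    """Query did not align to the reference above the identity floor."""


class MissingInterfacePositionError(IgxError):
    """One or more catalog interface positions fell on a gap."""

    def __init__(self, positions):
        self.positions = list(positions)
        labels = ", ".join(str(p) for p in self.positions)
        super().__init__(f"missing interface position(s): {labels}")


class MissingPositionError(IgxError):
    """A requested IMGT position is absent from a domain."""

    def __init__(self, domain_name, position):
        self.domain_name = domain_name
        self.position = position
        super().__init__(f"position {position} absent from {domain_name}")


class VariantNotApplicableError(IgxError):
    """A named variant rule found an unexpected residue at its target."""

    def __init__(self, variant, position, expected, observed):
        self.variant = variant
        self.position = position
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"variant {variant}: expected {expected} at {position}, found {observed}"
        )


class UnknownResidueError(IgxError):
    """A sequence letter outside the standard amino-acid alphabet."""
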