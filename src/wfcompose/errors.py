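"""Exception hierarchy shared by all wfcompose modules."""


class WfcomposeError(Exception):
    """Base class for all errors raised by this package."""


class TaxonomyError(WfcomposeError):
    """Malformed taxonomy: parse failure, dangling parent, cycle, bad branch."""


class LookupError_(WfcomposeError):
    """A concept or tool reference does not resolve."""


class ValidationError(WfcomposeError):
    """A domain model, specification or solution failed validation."""


class ConstraintSyntaxError(WfcomposeError):
    """A constraint string matches none of the supported templates."""


class ConstraintSemanticError(WfcomposeError):
    """A constraint template filler does not resolve in the domain model."""
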