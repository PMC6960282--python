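"""Package-wide exception type."""


class MisigError(ValueError):
    """Raised for invalid inputs or undefined results anywhere in the package.

    The message always starts with a short machine-greppable phrase
    (e.g. ``"duplicate gene id"``, ``"no protein-coding genes"``) followed by
    context.
    """
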