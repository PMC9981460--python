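"""Exception hierarchy shared across dilac modules."""


class DilacError(Exception):
    """Base class for all dilac-specific errors."""


class UnknownResidueError(DilacError, KeyError):
    """A one-letter code not present in the residue composition table."""


class PatternLengthError(DilacError, ValueError):
    """A labelling pattern whose length does not match the peptide's target-site count."""


class FragmentOrdinalError(DilacError, ValueError):
    """A fragment ordinal outside 1..len(peptide)-1."""


class UnknownProteaseError(DilacError, ValueError):
    """A protease name with no cleavage rule."""


class MissingColumnsError(DilacError, ValueError):
    """A tabular input lacking required columns; lists the absent names."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing required column(s): {', '.join(self.missing)}")


class UnnormalizedProfileError(DilacError, ValueError):
    """State fractions that do not sum to one."""


class UnquantifiableError(DilacError, ValueError):
    """No usable (diagnostic, nonzero) fragments remain for a peptide."""


class AllSamplesExcludedError(DilacError, ValueError):
    """Sample QC removed every sample."""
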