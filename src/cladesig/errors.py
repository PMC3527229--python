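"""Exception hierarchy for cladesig.

Every error raised on bad user input derives from :class:`CladesigError`,
so callers (and the CLI) can catch one type.
"""


class CladesigError(Exception):
    """Base class for all cladesig errors."""


class AlignmentShapeError(CladesigError):
    """Sequences in an alignment do not all have the same length."""


class IdCollisionError(CladesigError):
    """Two records in an input file share the same taxon id."""


class AlphabetError(CladesigError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""


class MetadataError(CladesigError):
    """A taxon is missing a required site code or other metadata."""


class StructureError(CladesigError):
    """A secondary-structure annotation is internally inconsistent."""


class StructureParseError(StructureError):
    """A CT / dot-bracket file cannot be parsed."""


class MappingError(CladesigError):
    """A reference coordinate cannot be lifted onto the alignment."""


class PartitionError(CladesigError):
    """A clade partition is invalid or references unknown labels."""


class CoordinateError(CladesigError):
    """An alignment-coordinate interval is out of bounds."""


class SitelhParseError(CladesigError):
    """A site-wise log-likelihood file is malformed."""


class TaxaError(CladesigError):
    """Tree and alignment taxon sets are incompatible."""


class PlantSpecError(CladesigError):
    """A planted-diagnostic specification cannot be realised."""
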