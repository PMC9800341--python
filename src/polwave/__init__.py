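"""polwave: 3'-end cleavage-site usage and Pol II elongation-rate analysis.

Submodules
----------
simulate    ground-truth generator for long-read 3' ends, DRB/TT-seq
            transcription-wave time courses and ChIP-style coverage
apa         proximal/distal polyadenylation-site usage quantification and
            per-gene classification between conditions
elongation  transcription-wave peak calling and elongation-rate regression
chip        anchored metagene profiles and sliding-window Poisson peak calling
io          readers/writers for BED6, bedGraph, GTF, chrom.sizes, FASTQ, TSV
coverage    in-memory genome coverage track container
pipeline    end-to-end orchestration with a reproducibility manifest
"""

from importlib.metadata import PackageNotFoundError, version

try:  # pragma: no cover
    __version__ = version("polwave")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


class PolwaveError(Exception):
    """Base class for all package errors."""


class ConfigError(PolwaveError):
    """Invalid configuration value or inconsistent parameter combination."""


class FormatError(PolwaveError):
    """Malformed input file; message names the file and line."""
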