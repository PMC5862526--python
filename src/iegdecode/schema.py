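"""Column-name and default-panel constants shared across the pipeline.

All tables are tidy long-format pandas DataFrames with fixed, documented
column names.  A "feature" is one (gene, structure) induction measurement.
"""

from __future__ import annotations

# Canonical column names for the raw Ct table (one row per mouse x
# structure x gene measurement).
MOUSE = "mouse_id"
STRUCTURE = "structure"
EXPERIENCE = "experience"
TIMEPOINT = "timepoint_hr"
CONTROL_GROUP = "control_group"
GENE = "gene"
CT = "ct"
DELTA_CT = "delta_ct"
FOLD = "fold"

CT_COLUMNS = [MOUSE, STRUCTURE, EXPERIENCE, TIMEPOINT, CONTROL_GROUP, GENE, CT]
FOLD_COLUMNS = [MOUSE, STRUCTURE, EXPERIENCE, CONTROL_GROUP, GENE, FOLD]

#: The five immediate-early genes of the default marker panel.
MARKER_GENES = ["Arc", "Egr2", "Egr4", "Fos", "Fosb"]

#: The five brain structures of the default decoding panel:
#: limbic cortex, nucleus accumbens, dorsal striatum, amygdala,
#: lateral hypothalamus.
STRUCTURES = ["LCtx", "NAc", "DS", "Amy", "LH"]

#: Stably expressed reference genes used to build the per-sample
#: global-normalization Ct value.
REFERENCE_GENES = [
    "Dkk3",
    "Tagln3",
    "Gars",
    "Scrn1",
    "Rpl36al",
    "Mcfd2",
    "Psma7",
    "Hpcla4",
]

#: Separator used when flattening a (gene, structure) feature into a
#: single column label, e.g. "Arc:LCtx".
FEATURE_SEP = ":"


def feature_name(gene: str, structure: str) -> str:
    return f"{gene}{FEATURE_SEP}{structure}"


def split_feature(name: str) -> tuple[str, str]:
    gene, _, structure = name.partition(FEATURE_SEP)
    if not structure:
        raise ValueError(f"not a gene{FEATURE_SEP}structure feature name: {name!r}")
    return gene, structure
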