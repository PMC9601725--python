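"""Fixed quantities of the gastrointestinal-cancer readmission study.

The analysis runs on eight categorical variables describing a cohort of
gastrointestinal-cancer patients on active chemotherapy: cancer site, body
mass index class, bone metastasis, serum albumin class, nutritional support,
breakthrough-cancer-pain (BTcP) predictability, radiotherapy, and the
unplanned hospital-readmission (HRA) count class. This module collects their
level sets, the clinical cut points, the prior-knowledge arc constraints,
and the two reference network structures (the knowledge-based DAG and the
score-selected one).
"""

from __future__ import annotations

from .cohort import CohortSchema, DiscretizationRule, VariableSpec
from .dag import DAG, ConstraintSet, dag_from_factorization

__all__ = [
    "BMI", "CANCER", "MTX", "ALB", "NUTR", "BTCP", "RADIO", "HRA",
    "VARIABLES", "VARIABLE_NAMES",
    "BIC_FACTORIZATION", "bic_dag", "knowledge_dag",
    "study_constraints", "discretization_rules", "raw_schema", "analysis_schema",
]

BMI = VariableSpec("BMI", ("<25 kg/m2", "≥25 kg/m2"))
CANCER = VariableSpec(
    "CANCER",
    ("Esophageal or gastric", "Colon-rectum", "Pancreas, gallbladder, biliary tract"),
)
MTX = VariableSpec("MTX", ("No", "Yes"))
ALB = VariableSpec("ALB", ("≤3.5 g/dL", ">3.5 g/dL"))
NUTR = VariableSpec("NUTR", ("No", "Yes"))
BTCP = VariableSpec("BTcP", ("Not predictable", "Predictable"))
RADIO = VariableSpec("RADIO", ("No", "Yes"))
HRA = VariableSpec("HRA", ("≤10", "11–22", ">22"), ordered=True)

VARIABLES: tuple[VariableSpec, ...] = (BMI, CANCER, MTX, ALB, NUTR, BTCP, RADIO, HRA)
VARIABLE_NAMES: tuple[str, ...] = tuple(v.name for v in VARIABLES)

#: The score-selected factorization:
#: P(BMI)·P(ALB)·P(CANCER)·P(MTX|CANCER)·P(NUTR|ALB)·P(BTcP|MTX,BMI)
#: ·P(RADIO|MTX)·P(HRA|NUTR,RADIO)
BIC_FACTORIZATION: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("BMI", ()),
    ("ALB", ()),
    ("CANCER", ()),
    ("MTX", ("CANCER",)),
    ("NUTR", ("ALB",)),
    ("BTcP", ("MTX", "BMI")),
    ("RADIO", ("MTX",)),
    ("HRA", ("NUTR", "RADIO")),
)


def bic_dag() -> DAG:
    """The 7-arc DAG read off the score-selected factorization."""
    return dag_from_factorization(BIC_FACTORIZATION)


def knowledge_dag() -> DAG:
    """The hypothesized clinical-knowledge DAG (11 arcs).

    Arcs realize the a-priori association list — BMI–BTcP; cancer type with
    metastasis, nutrition and readmissions; metastasis with nutrition, BTcP
    and radiotherapy; albumin with nutrition; nutrition and radiotherapy with
    readmissions; radiotherapy with nutrition — oriented causally (causes
    point at effects; radiotherapy toward nutritional need via treatment
    burden). The readmission node keeps radiotherapy and nutritional support
    as direct parents.
    """
    arcs = [
        ("BMI", "BTcP"),
        ("CANCER", "MTX"),
        ("CANCER", "NUTR"),
        ("CANCER", "HRA"),
        ("ALB", "NUTR"),
        ("MTX", "NUTR"),
        ("MTX", "BTcP"),
        ("MTX", "RADIO"),
        ("RADIO", "NUTR"),
        ("NUTR", "HRA"),
        ("RADIO", "HRA"),
    ]
    return DAG(VARIABLE_NAMES, arcs)


def study_constraints() -> ConstraintSet:
    """Prior clinical constraints on the arc search.

    Whitelist (must hold): higher BMI predisposes to (non-predictable) BTcP;
    bone metastases induce BTcP and palliative radiotherapy; albumin status
    drives nutritional support. Blacklist (impossible): nothing causes the
    tumor type; albumin and nutritional support cause neither BTcP nor bone
    metastasis.
    """
    whitelist = frozenset(
        {("BMI", "BTcP"), ("MTX", "BTcP"), ("MTX", "RADIO"), ("ALB", "NUTR")}
    )
    blacklist = frozenset(
        {(v, "CANCER") for v in VARIABLE_NAMES if v != "CANCER"}
        | {("ALB", "BTcP"), ("NUTR", "BTcP"), ("ALB", "MTX"), ("NUTR", "MTX")}
    )
    return ConstraintSet(whitelist, blacklist)


def discretization_rules() -> tuple[DiscretizationRule, ...]:
    """Clinical cut points for the three measured quantities.

    BMI at 25 kg/m2 with the boundary in the upper class (25.0 is "≥25");
    serum albumin at 3.5 g/dL with the boundary in the lower class; HRA
    count at 10 and 22, boundaries in the lower classes (10 is "≤10",
    22 is "11–22").
    """
    return (
        DiscretizationRule("BMI", (25.0,), BMI, right_closed=False, units="kg/m2"),
        DiscretizationRule("ALB", (3.5,), ALB, right_closed=True, units="g/dL"),
        DiscretizationRule("HRA", (10.0, 22.0), HRA, right_closed=True, units="count"),
    )


def raw_schema() -> CohortSchema:
    """Input layout before discretization: 5 categorical + 3 numeric columns."""
    return CohortSchema(
        categorical=(CANCER, MTX, NUTR, BTCP, RADIO),
        numeric=("BMI", "ALB", "HRA"),
    )


def analysis_schema() -> CohortSchema:
    """Layout of the fully categorical 8-variable analysis table."""
    return CohortSchema(categorical=VARIABLES)
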