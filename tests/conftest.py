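import random

import pytest

from afp.corpus import Article, EntityType, LexiconEntry
from afp.extraction import MatchRuleSet


@pytest.fixture
def tiny_lexicons() -> dict[EntityType, list[LexiconEntry]]:
    """Hand-built lexicons covering all five types and the special rules."""
    return {
        EntityType.GENE: [
            LexiconEntry(EntityType.GENE, "WBGene00002992", "lin-3", ("F36H1.4",)),
            LexiconEntry(EntityType.GENE, "WBGene00002299", "let-23"),
            LexiconEntry(EntityType.GENE, "WBGene00006789", "unc-26"),
        ],
        EntityType.ALLELE: [
            LexiconEntry(EntityType.ALLELE, "WBVar00000001", "sy53"),
            LexiconEntry(EntityType.ALLELE, "WBVar00000002", "n1059"),
            LexiconEntry(EntityType.ALLELE, "WBVar00000003", "m2"),
        ],
        EntityType.STRAIN: [
            LexiconEntry(EntityType.STRAIN, "WBStrain00000001", "CB1417"),
            LexiconEntry(EntityType.STRAIN, "WBStrain00000002", "MT1348"),
        ],
        EntityType.TRANSGENE: [
            LexiconEntry(EntityType.TRANSGENE, "WBTransgene00000001", "syIs107"),
            LexiconEntry(EntityType.TRANSGENE, "WBTransgene00000002", "zhEx68"),
        ],
        EntityType.SPECIES: [
            LexiconEntry(EntityType.SPECIES, "NCBITaxon:6239", "Caenorhabditis elegans"),
            LexiconEntry(EntityType.SPECIES, "NCBITaxon:7227", "Drosophila melanogaster"),
            LexiconEntry(EntityType.SPECIES, "NCBITaxon:7955", "Danio rerio"),
        ],
    }


@pytest.fixture
def rules() -> MatchRuleSet:
    return MatchRuleSet()


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)


def make_article(paper_id="WBPaper00000001", title="", abstract="", body=""):
    return Article(paper_id=paper_id, title=title, abstract=abstract, body=body)
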