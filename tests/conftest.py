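from __future__ import annotations

import numpy as np
import pytest

from auccaliper.corpus_io import AbstractRecord

THREE_CITATION_XML = b"""<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1001</PMID>
      <Article>
        <Journal><Title>PLoS One</Title>
          <JournalIssue><PubDate><Year>2019</Year></PubDate></JournalIssue>
        </Journal>
        <ArticleTitle>A prediction model for sepsis</ArticleTitle>
        <Abstract>
          <AbstractText Label="BACKGROUND">Sepsis prediction remains difficult in practice.</AbstractText>
          <AbstractText Label="METHODS">We fitted a logistic regression model to registry data.</AbstractText>
          <AbstractText Label="RESULTS">The AUC was 0.82 in internal validation of the model.</AbstractText>
        </Abstract>
        <PublicationTypeList><PublicationType>Journal Article</PublicationType></PublicationTypeList>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Humans</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>ROC Curve</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1002</PMID>
      <Article>
        <Journal><Title>Journal of Empty Abstracts</Title>
          <JournalIssue><PubDate><MedlineDate>2004 Jan-Feb</MedlineDate></PubDate></JournalIssue>
        </Journal>
        <ArticleTitle>A citation without abstract text</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1003</PMID>
      <Article>
        <Journal><Title>Clinical Pharmacology Letters</Title>
          <JournalIssue><PubDate><Year>2015</Year></PubDate></JournalIssue>
        </Journal>
        <ArticleTitle>Pharmacokinetics of drug Z</ArticleTitle>
        <Abstract>
          <AbstractText>The AUC0-24 was 412 ng\xc2\xb7h/mL after repeated dosing in twelve healthy adult volunteers overall.</AbstractText>
        </Abstract>
        <PublicationTypeList><PublicationType>Clinical Trial</PublicationType></PublicationTypeList>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Pharmacokinetics</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def three_citation_xml() -> bytes:
    return THREE_CITATION_XML


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def make_record(
    text: str = "",
    label: str = "RESULTS",
    pmid: str = "1",
    sections: tuple | None = None,
    **kwargs,
) -> AbstractRecord:
    if sections is None:
        sections = ((label, text),) if text else ()
    return AbstractRecord(pmid=pmid, sections=sections, **kwargs)


@pytest.fixture
def record_factory():
    return make_record
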