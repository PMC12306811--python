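"""Reader adapters mapping external records onto litmine domain types.

Two formats are supported: PubMed efetch XML (``PubmedArticleSet``) and
ClinicalTrials.gov API v2 study JSON.  The parsers are pure functions over
already-fetched payloads; the fetch helpers at the bottom require network
access and exist only as runtime conveniences.
"""

from __future__ import annotations

import datetime
import json
import logging
import re
import urllib.parse
import urllib.request
from typing import Optional

from lxml import etree

from .corpus_model import (ArmRecord, GroupSpec, ParticipantMeasureTruth,
                           ParticipantValue, RegistryData, StudyRecord,
                           TrialResultTruth, TrialResultValue)

logger = logging.getLogger(__name__)

_MONTHS = {m: i + 1 for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"])}


def _parse_pubdate(node) -> Optional[datetime.date]:
    if node is None:
        return None
    year = node.findtext("Year")
    if not year:
        return None
    month_text = node.findtext("Month") or "Jan"
    month = (_MONTHS.get(month_text[:3].title())
             or (int(month_text) if month_text.isdigit() else 1))
    day = node.findtext("Day")
    try:
        return datetime.date(int(year), month, int(day) if day else 1)
    except ValueError:
        return None


_NCT_RE = re.compile(r"NCT\d{8}")


def parse_pubmed_xml(xml_text: str | bytes) -> list[StudyRecord]:
    """Publication records from a PubMed efetch ``PubmedArticleSet``
    payload.  An NCT id mentioned in the data-bank list or abstract becomes
    the registry link."""
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    root = etree.fromstring(xml_text)
    records: list[StudyRecord] = []
    for article in root.iter("PubmedArticle"):
        pmid = article.findtext(".//PMID")
        if not pmid:
            logger.warning("PubmedArticle without PMID skipped")
            continue
        title = article.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (t.text or "") for t in article.iter("AbstractText")).strip()
        pub_date = _parse_pubdate(article.find(".//JournalIssue/PubDate"))
        nct = None
        for acc in article.iter("AccessionNumber"):
            if acc.text and _NCT_RE.fullmatch(acc.text.strip()):
                nct = acc.text.strip()
                break
        if nct is None:
            m = _NCT_RE.search(abstract)
            nct = m.group(0) if m else None
        records.append(StudyRecord(
            study_id=pmid.strip(), kind="publication", title=title,
            abstract=abstract, pub_date=pub_date, nct_link=nct))
    return records


def _num(value) -> Optional[float]:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def parse_ctgov_study(payload: dict | str) -> StudyRecord:
    """A trial-registry record from a ClinicalTrials.gov API v2 study JSON
    document, including structured results when reported."""
    if isinstance(payload, str):
        payload = json.loads(payload)
    protocol = payload.get("protocolSection", {})
    ident = protocol.get("identificationModule", {})
    nct = ident.get("nctId", "")
    design = protocol.get("designModule", {})
    arms_module = protocol.get("armsInterventionsModule", {})
    arms = [ArmRecord(
        label=a.get("label", f"arm {i}"),
        arm_type=a.get("type", ""),
        description=a.get("description", ""),
        intervention_names=a.get("interventionNames", []),
    ) for i, a in enumerate(arms_module.get("armGroups", []))]

    results = payload.get("resultsSection", {})
    measures: list[ParticipantMeasureTruth] = []
    baseline = results.get("baselineCharacteristicsModule", {})
    groups = [GroupSpec(group_id=g.get("id", f"BG{i:03d}"),
                        definition=g.get("description", g.get("title", "")))
              for i, g in enumerate(baseline.get("groups", []))]
    for measure in baseline.get("measures", []):
        values: list[ParticipantValue] = []
        for cls in measure.get("classes", []):
            for cat in cls.get("categories", []):
                for m in cat.get("measurements", []):
                    v = _num(m.get("value"))
                    if v is not None:
                        values.append(ParticipantValue(
                            group_id=m.get("groupId", ""), value=v))
        if values:
            measures.append(ParticipantMeasureTruth(
                measure_definition=measure.get("title", ""),
                parameter_type=measure.get("paramType", ""),
                unit=measure.get("unitOfMeasure", ""),
                groups=groups or [GroupSpec(group_id=v.group_id)
                                  for v in values],
                results=values))

    outcomes: list[TrialResultTruth] = []
    for om in results.get("outcomeMeasuresModule", {}).get(
            "outcomeMeasures", []):
        values = []
        group_titles = {g.get("id"): g.get("title", "")
                        for g in om.get("groups", [])}
        for cls in om.get("classes", []):
            for cat in cls.get("categories", []):
                for m in cat.get("measurements", []):
                    v = _num(m.get("value"))
                    if v is not None:
                        values.append(TrialResultValue(
                            value=v,
                            title=group_titles.get(m.get("groupId"), "")))
        if values:
            outcomes.append(TrialResultTruth(
                outcome_definition=om.get("title", ""),
                group_definition="; ".join(
                    g.get("title", "") for g in om.get("groups", [])),
                parameter_type=om.get("paramType", ""),
                unit=om.get("unitOfMeasure", ""),
                timeframe=om.get("timeFrame", ""),
                results=values))

    truth = RegistryData(
        conditions=protocol.get("conditionsModule", {}).get("conditions", []),
        interventions=[i.get("name", "") for i in
                       arms_module.get("interventions", [])],
        enrollment=int(design.get("enrollmentInfo", {}).get("count", 0) or 0),
        study_type=design.get("studyType", ""),
        arms=arms, participant_measures=measures, outcome_results=outcomes)
    brief = ident.get("briefTitle", "")
    summary = (protocol.get("descriptionModule", {})
               .get("briefSummary", ""))
    return StudyRecord(study_id=nct, kind="trial_registry", title=brief,
                       abstract=summary, registry_truth=truth)


# ---------------------------------------------------------------------------
# Network fetch helpers (optional; never used by the test suite)
# ---------------------------------------------------------------------------

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
CTGOV = "https://clinicaltrials.gov/api/v2/studies"


def fetch_pubmed(query: str, retmax: int = 100,
                 timeout: float = 60.0) -> list[StudyRecord]:
    """Run a serialized boolean query against PubMed esearch+efetch."""
    search_url = (f"{EUTILS}/esearch.fcgi?db=pubmed&retmax={retmax}&term="
                  + urllib.parse.quote(query))
    with urllib.request.urlopen(search_url, timeout=timeout) as resp:
        ids = [e.text for e in etree.fromstring(resp.read()).iter("Id")]
    if not ids:
        return []
    fetch_url = (f"{EUTILS}/efetch.fcgi?db=pubmed&retmode=xml&id="
                 + ",".join(ids))
    with urllib.request.urlopen(fetch_url, timeout=timeout) as resp:
        return parse_pubmed_xml(resp.read())


def fetch_ctgov(term: str, page_size: int = 50,
                timeout: float = 60.0) -> list[StudyRecord]:
    """Query ClinicalTrials.gov v2 with a term expression."""
    url = (f"{CTGOV}?pageSize={page_size}&query.term="
           + urllib.parse.quote(term))
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        payload = json.loads(resp.read().decode("utf-8"))
    return [parse_ctgov_study(s) for s in payload.get("studies", [])]
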