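"""Synthetic Finnish-style smoking-sentence corpus.

Generates labeled sentences of the four smoking-status classes from
template families with token-slot fillers (dates, cigarette counts,
pack-years).  The Finnish word stems ``tupak``/``aski`` and English
``smok`` appear verbatim so the downstream stem filter is exercised; other
tokens may be pseudo-Finnish.  Template families deliberately cover the
hard boundary cases of real clinical notes: "quit smoking <date>" is an
ex-smoker sentence, while "quit smoking recently" (no date) and pack-year
histories are unknown.  Character-level noise at a configurable rate makes
the classes learnable but not memorizable; noise never destroys the last
intact stem token of a non-unknown sentence, preserving the stem invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np

from .nlp import CLASS_ORDER, SMOKING_STEMS, LabeledSentence

_ALPHABET = "abcdefghijklmnopqrstuvwxyzäö"

# Template families per class. Slots: {cigs} cigarettes/day, {packs} packs,
# {month}/{yy} short quit dates, {year} four-digit years, {ago} years ago,
# {packyears} pack-year totals.
TEMPLATES: dict[str, tuple[str, ...]] = {
    "current": (
        "potilas tupakoi {cigs} savuketta paivassa",
        "tupakoi edelleen {cigs} paivassa",
        "polttaa noin {packs} askia paivassa",
        "tupakointi jatkuu edelleen paivittain",
        "smokes about {cigs} cigarettes daily",
        "potilas on tupakoitsija polttaa saannollisesti",
        "tupakoi satunnaisesti viikonloppuisin edelleen",
        "aski paivassa kuluu edelleen",
        "current smoker {cigs} per day",
        "tupakointi paivittaista noin {packs} askia",
    ),
    "ex": (
        "lopettanut tupakoinnin {month} {yy}",
        "tupakoinnin lopetus vuonna {year}",
        "ex tupakoitsija lopetti vuonna {year}",
        "stopped smoking {month} {yy}",
        "smoked {year} {year2} sitten lopettanut",
        "tupakoinut aiemmin lopetti {year}",
        "lopetti tupakan {ago} vuotta sitten",
        "aski paivassa kunnes lopetti {year}",
        "quit smoking in {year}",
    ),
    "never": (
        "ei ole koskaan tupakoinut",
        "potilas ei tupakoi eika ole koskaan tupakoinut",
        "never smoked no tobacco use",
        "tupakointi ei koskaan aloittanut",
        "ei tupakoi ei askihistoriaa",
        "kieltaa tupakoinnin kokonaan ei koskaan",
        "has never smoked any cigarettes",
        "tupakka ei kuulu tapoihin ei koskaan polttanut",
        "ei tupakoi eika ole koskaan polttanut",
    ),
    "unknown": (
        "lopettanut tupakoinnin hiljattain",
        "on tupakoinut aiemmin",
        "tupakointi {packyears} askivuotta",
        "pitka tupakkahistoria taustalla",
        "lopettanut tupakoinnin vastikaan",
        "smoking history unclear",
        "tupakoinnista ei tarkempaa tietoa",
        "kayttaa sahkotupakkaa paivittain",
        "stopped smoking recently",
        "askivuosia kertynyt runsaasti",
    ),
}


@dataclass(frozen=True)
class CorpusConfig:
    """Generator settings for the sentence corpus.

    ``class_mix`` orders probabilities as CLASS_ORDER
    (current, ex, never, unknown); ``noise_rate`` is the per-token
    probability of one character-level perturbation.
    """

    n_sentences: int = 10_000
    class_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences <= 0:
            raise ValueError("n_sentences must be positive")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (4,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mix must be 4 non-negative numbers summing to 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")


def _fill_slots(template: str, rng: np.random.Generator) -> str:
    year = int(rng.integers(1975, 2020))
    return template.format(
        cigs=int(rng.integers(1, 41)),
        packs=int(rng.integers(1, 4)),
        month=int(rng.integers(1, 13)),
        yy=f"{int(rng.integers(0, 22)):02d}",
        year=year,
        year2=int(rng.integers(year + 1, 2021)),
        ago=int(rng.integers(1, 31)),
        packyears=int(rng.integers(5, 61)),
    )


def _perturb_token(token: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(token)))
    op = rng.integers(0, 3)
    if op == 0:  # substitute
        ch = _ALPHABET[int(rng.integers(0, len(_ALPHABET)))]
        return token[:pos] + ch + token[pos + 1 :]
    if op == 1 and len(token) > 1:  # delete
        return token[:pos] + token[pos + 1 :]
    return token[:pos] + token[pos] + token[pos:]  # duplicate


def _apply_noise(
    text: str, noise_rate: float, protect_stem: bool, rng: np.random.Generator
) -> str:
    if noise_rate == 0.0:
        return text
    tokens = text.split()
    stem_idx = [
        i
        for i, t in enumerate(tokens)
        if any(t.startswith(s) for s in SMOKING_STEMS)
    ]
    # one stem token stays intact so the stem filter keeps the sentence
    protected = {stem_idx[int(rng.integers(0, len(stem_idx)))]} if (
        protect_stem and stem_idx
    ) else set()
    out = []
    for i, tok in enumerate(tokens):
        if i not in protected and rng.random() < noise_rate:
            tok = _perturb_token(tok, rng)
        out.append(tok)
    return " ".join(t for t in out if t)


def generate_corpus(config: CorpusConfig) -> list[LabeledSentence]:
    """Draw a labeled corpus; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    label_idx = rng.choice(4, size=config.n_sentences, p=np.asarray(config.class_mix))
    base = date(2014, 1, 1)
    sentences = []
    for i, li in enumerate(label_idx):
        label = CLASS_ORDER[li]
        sentences.append(
            LabeledSentence(
                patient_id=f"corpus-{i:06d}",
                timestamp=base + timedelta(days=int(rng.integers(0, 6 * 365))),
                text=render_sentence(label, rng, noise_rate=config.noise_rate),
                label=label,
            )
        )
    return sentences


def render_sentence(
    label: str, rng: np.random.Generator, noise_rate: float = 0.0
) -> str:
    """One sentence of the given class from a random template family."""
    templates = TEMPLATES[label]
    text = _fill_slots(templates[int(rng.integers(0, len(templates)))], rng)
    return _apply_noise(text, noise_rate, protect_stem=label != "unknown", rng=rng)


# ---------------------------------------------------------------------------
# JSONL I/O

def write_corpus_jsonl(sentences: Sequence[LabeledSentence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(
                json.dumps(
                    {
                        "patient_id": s.patient_id,
                        "timestamp": s.timestamp.isoformat(),
                        "text": s.text,
                        "label": s.label,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path) -> list[LabeledSentence]:
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            sentences.append(
                LabeledSentence(
                    patient_id=obj["patient_id"],
                    timestamp=date.fromisoformat(obj["timestamp"]),
                    text=obj["text"],
                    label=obj.get("label"),
                )
            )
    return sentences
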