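"""Optional pretrained bidirectional-encoder embedding backend.

Requires the optional ``transformers`` and ``torch`` packages plus
downloaded weights; nothing in the default pipeline or test suite imports
them. The backend satisfies the :class:`speechphen.coherence.EmbeddingBackend`
contract: per-word vectors from the encoder's last hidden state (word-piece
vectors mean-pooled back to whitespace words) and the model's
next-sentence-prediction head for pair probabilities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["TransformerBackend"]


class TransformerBackend:
    def __init__(self, model_name: str = "bert-base-uncased"):
        try:
            import torch  # noqa: PLC0415
            from transformers import (  # noqa: PLC0415
                AutoTokenizer,
                BertForNextSentencePrediction,
                BertModel,
            )
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "TransformerBackend requires the optional 'transformers' and "
                "'torch' packages; use speechphen.synthetic.toy_backend() for "
                "a hermetic backend"
            ) from exc
        self._torch = torch
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._encoder = BertModel.from_pretrained(model_name).eval()
        self._nsp = BertForNextSentencePrediction.from_pretrained(model_name).eval()

    def embed_words(self, words: Sequence[str]) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        enc = self._tokenizer(
            list(words), is_split_into_words=True, return_tensors="pt"
        )
        with torch.no_grad():
            hidden = self._encoder(**enc).last_hidden_state[0]
        vectors = []
        word_ids = enc.word_ids(0)
        for i in range(len(words)):
            piece_idx = [j for j, w in enumerate(word_ids) if w == i]
            vectors.append(hidden[piece_idx].mean(dim=0).numpy())
        return np.vstack(vectors)

    def next_sentence_probability(
        self, first: Sequence[str], second: Sequence[str]
    ) -> float:  # pragma: no cover
        torch = self._torch
        enc = self._tokenizer(" ".join(first), " ".join(second), return_tensors="pt")
        with torch.no_grad():
            logits = self._nsp(**enc).logits
        # index 0 of the NSP head is the "is next" class
        return float(torch.softmax(logits, dim=1)[0, 0])
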