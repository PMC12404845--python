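"""Uniform completion contract over interchangeable backends.

Ships a deterministic offline mock (the only backend the test suite needs),
a response cache, and thin HTTP adapters for OpenAI-compatible vendors. The
mock answers eligibility prompts by scanning the embedded document for
fixture sentinels («INC», «EXC:dimension») and can flip a seed-determined
fraction of records to emulate an imperfect model.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
import time
import urllib.request
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

from .criteria_prompt import DIMENSION_MARKER, DOCUMENT_MARKER
from .errors import BackendUnavailableError, TransportError

SENTINEL_INCLUDE = "«INC»"
_SENTINEL_EXCLUDE = re.compile(r"«EXC:([a-z_]+)»")


@dataclass
class BackendParams:
    model_name: str = "mock"
    temperature: float = 0.0
    timeout_s: float = 60.0
    max_retries: int = 2
    max_concurrency: int = 1

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")
        if self.max_concurrency < 1:
            raise ValueError("max_concurrency must be >= 1")


@dataclass
class CompletionResult:
    text: str
    backend_name: str
    latency_s: float
    attempt_count: int


class Backend(Protocol):
    name: str

    def generate(self, prompt: str, params: BackendParams) -> str: ...


# ---------------------------------------------------------------------------
# retry wrapper


def complete(
    prompt: str,
    backend: Backend,
    params: BackendParams,
    _sleep: Callable[[float], None] = time.sleep,
) -> CompletionResult:
    """Call the backend with exponential-backoff retries on transport failure.

    Semantically wrong but well-formed answers are returned as-is — repairing
    those is the parser's job, not the transport's.
    """
    if not prompt:
        raise ValueError("prompt must be non-empty")
    start = time.perf_counter()
    last: Exception | None = None
    for attempt in range(params.max_retries + 1):
        try:
            text = backend.generate(prompt, params)
        except TransportError as exc:
            last = exc
            if attempt < params.max_retries:
                _sleep(min(0.1 * 2**attempt, 2.0))
            continue
        return CompletionResult(
            text=text,
            backend_name=backend.name,
            latency_s=time.perf_counter() - start,
            attempt_count=attempt + 1,
        )
    raise BackendUnavailableError(
        f"backend {backend.name!r} unavailable after {params.max_retries + 1} attempt(s): {last}"
    )


def complete_many(
    prompts: Sequence[str], backend: Backend, params: BackendParams
) -> list[CompletionResult]:
    """At most ``max_concurrency`` in-flight requests; results returned in
    submission order."""
    with ThreadPoolExecutor(max_workers=params.max_concurrency) as pool:
        futures = [pool.submit(complete, p, backend, params) for p in prompts]
        return [f.result() for f in futures]


# ---------------------------------------------------------------------------
# deterministic offline mock


def _document_of(prompt: str) -> str:
    marker = f"{DOCUMENT_MARKER}\n"
    pos = prompt.find(marker)
    return prompt[pos + len(marker) :] if pos != -1 else prompt


def _dimension_of(prompt: str) -> str | None:
    for line in prompt.splitlines():
        if line.startswith(DIMENSION_MARKER):
            return line[len(DIMENSION_MARKER) :].strip()
    return None


def _unit_hash(text: str, seed: int) -> float:
    digest = hashlib.blake2b(
        text.encode("utf-8"), digest_size=8, key=str(seed).encode()
    ).digest()
    return int.from_bytes(digest, "big") / 2**64


def mock_complete(prompt: str, noise: float = 0.0, seed: int = 0) -> str:
    """Answer an eligibility prompt from fixture sentinels in the document.

    With noise ε > 0, a deterministic pseudo-random ε-fraction of documents
    (keyed on document text + seed, so all chained tasks for one record agree)
    has its final include/exclude verdict flipped.
    """
    document = _document_of(prompt)
    dimension = _dimension_of(prompt)
    gold_exclude_dims = set(_SENTINEL_EXCLUDE.findall(document))
    flipped = noise > 0 and _unit_hash(document, seed) < noise
    if flipped:
        # gold include → fail whatever task is asked first (record excluded);
        # gold exclude → pass every task (record included).
        fail = not gold_exclude_dims
    else:
        fail = dimension in gold_exclude_dims
    answer = {
        "criterion_met": "no" if fail else "yes",
        "rationale": (
            f"mock verdict for dimension {dimension or 'unknown'}"
            + (" (noise-flipped)" if flipped else "")
        ),
    }
    return json.dumps(answer, ensure_ascii=False)


class MockBackend:
    """Offline test double: deterministic at temperature 0, seedable noise."""

    def __init__(self, noise: float = 0.0, seed: int = 0, name: str = "mock"):
        if not 0 <= noise < 1:
            raise ValueError("noise must be in [0, 1)")
        self.noise = noise
        self.seed = seed
        self.name = name

    def generate(self, prompt: str, params: BackendParams) -> str:
        return mock_complete(prompt, noise=self.noise, seed=self.seed)


# ---------------------------------------------------------------------------
# response cache


class CachedBackend:
    """Caches completions on (backend, model_name, prompt) for cheap,
    deterministic reruns."""

    def __init__(self, inner: Backend, cache_dir: str | Path):
        self.inner = inner
        self.name = inner.name
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)

    def _path(self, prompt: str, params: BackendParams) -> Path:
        key = hashlib.sha256(
            f"{self.inner.name}|{params.model_name}|{prompt}".encode()
        ).hexdigest()
        return self.cache_dir / f"{key}.json"

    def generate(self, prompt: str, params: BackendParams) -> str:
        path = self._path(prompt, params)
        if path.exists():
            return json.loads(path.read_text(encoding="utf-8"))["text"]
        text = self.inner.generate(prompt, params)
        path.write_text(json.dumps({"text": text}, ensure_ascii=False), encoding="utf-8")
        return text


# ---------------------------------------------------------------------------
# vendor adapters (excluded from the test path; credentials via environment)


class OpenAICompatibleBackend:  # pragma: no cover - requires network
    """Chat-completions adapter for OpenAI-dialect HTTP APIs."""

    def __init__(
        self,
        base_url: str = "https://api.openai.com/v1",
        api_key_env: str = "OPENAI_API_KEY",
        name: str = "openai",
    ):
        self.base_url = base_url.rstrip("/")
        self.api_key_env = api_key_env
        self.name = name

    def generate(self, prompt: str, params: BackendParams) -> str:
        api_key = os.environ.get(self.api_key_env)
        if not api_key:
            raise TransportError(f"missing credential env var {self.api_key_env}")
        payload = json.dumps(
            {
                "model": params.model_name,
                "temperature": params.temperature,
                "messages": [{"role": "user", "content": prompt}],
            }
        ).encode()
        request = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=payload,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {api_key}",
            },
        )
        try:
            with urllib.request.urlopen(request, timeout=params.timeout_s) as resp:
                body = json.loads(resp.read().decode())
        except Exception as exc:
            raise TransportError(f"{self.name} request failed: {exc}") from exc
        try:
            return body["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise TransportError(f"{self.name} malformed transport envelope") from exc


class MoonshotBackend(OpenAICompatibleBackend):  # pragma: no cover
    def __init__(self) -> None:
        super().__init__(
            base_url="https://api.moonshot.cn/v1",
            api_key_env="MOONSHOT_API_KEY",
            name="moonshot",
        )


class DeepSeekBackend(OpenAICompatibleBackend):  # pragma: no cover
    def __init__(self) -> None:
        super().__init__(
            base_url="https://api.deepseek.com/v1",
            api_key_env="DEEPSEEK_API_KEY",
            name="deepseek",
        )
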