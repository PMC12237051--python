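"""Minimal REST front of the provenance builder.

Endpoints (JSON in/out):

* ``POST /events``  — one event; ``202`` accepted, ``200`` rejected (the
  rejection record is kept in the error log), ``409`` duplicate.
* ``GET /graph``    — the current graph as PROV-JSON.
* ``GET /errors``   — the error-log records.
* ``GET /export?format=prov-json|dot``

Built on the standard library's threading HTTP server; requests are
serialized through one lock so ingestion order is well defined.
"""

from __future__ import annotations

import json
import threading
import urllib.error
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, urlparse

from .builder import (
    BuilderState,
    DuplicateEventError,
    Event,
    MalformedEventError,
    MissingFieldError,
    parse_event,
    ingest_event,
)
from .patterns import MatchViolation
from .views import export_dot, export_prov_json

__all__ = ["make_server", "serve", "post_event"]


class _Handler(BaseHTTPRequestHandler):
    server_version = "studyprov/0.1"

    def _send(self, code: int, body: str, content_type: str = "application/json") -> None:
        data = body.encode("utf-8")
        self.send_response(code)
        self.send_header("Content-Type", content_type)
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)

    def _json(self, code: int, obj) -> None:
        self._send(code, json.dumps(obj, sort_keys=True))

    def log_message(self, fmt, *args):  # route access logs to stderr quietly
        pass

    def do_POST(self) -> None:
        if urlparse(self.path).path != "/events":
            self._json(404, {"error": "unknown endpoint"})
            return
        length = int(self.headers.get("Content-Length", 0))
        raw = self.rfile.read(length).decode("utf-8")
        state: BuilderState = self.server.state
        with self.server.lock:
            try:
                event = parse_event(raw)
            except (MalformedEventError, MissingFieldError) as exc:
                from .builder import ErrorLogRecord
                import hashlib

                surrogate = f"post-{hashlib.sha1(raw.encode()).hexdigest()[:8]}"
                state.error_log.append(
                    ErrorLogRecord(
                        event_text=raw,
                        violations=(MatchViolation("malformed-event", str(exc)),),
                        received_at=state.clock(),
                        event_id=surrogate,
                    )
                )
                state.processed_event_ids.add(surrogate)
                self._json(200, {"status": "rejected", "violations": [str(exc)]})
                return
            try:
                before = len(state.error_log)
                ingest_event(state, event)
            except DuplicateEventError as exc:
                self._json(409, {"status": "duplicate", "detail": str(exc)})
                return
            if len(state.error_log) > before:
                record = state.error_log[-1]
                self._json(
                    200,
                    {
                        "status": "rejected",
                        "violations": [v.to_dict() for v in record.violations],
                    },
                )
            else:
                self._json(202, {"status": "accepted", "event_id": event.event_id})

    def do_GET(self) -> None:
        parsed = urlparse(self.path)
        state: BuilderState = self.server.state
        with self.server.lock:
            if parsed.path == "/graph":
                self._send(200, export_prov_json(state.graph))
            elif parsed.path == "/errors":
                self._json(200, [r.to_dict() for r in state.error_log])
            elif parsed.path == "/export":
                fmt = parse_qs(parsed.query).get("format", ["prov-json"])[0]
                if fmt == "prov-json":
                    self._send(200, export_prov_json(state.graph))
                elif fmt == "dot":
                    self._send(200, export_dot(state.graph), "text/vnd.graphviz")
                else:
                    self._json(400, {"error": f"unknown format {fmt!r}"})
            else:
                self._json(404, {"error": "unknown endpoint"})


def make_server(state: BuilderState, host: str = "127.0.0.1", port: int = 0) -> ThreadingHTTPServer:
    """Create (but do not start) the builder HTTP server; ``port=0`` picks
    a free port (``server.server_address`` reports it)."""
    server = ThreadingHTTPServer((host, port), _Handler)
    server.state = state
    server.lock = threading.Lock()
    return server


def serve(state: BuilderState, host: str = "127.0.0.1", port: int = 8140) -> None:
    """Run the builder service until interrupted."""
    server = make_server(state, host, port)
    try:
        server.serve_forever()
    finally:
        server.server_close()


def post_event(base_url: str, event: Event, timeout: float = 10.0) -> dict:
    """Client helper: POST one event to a running builder service."""
    req = urllib.request.Request(
        base_url.rstrip("/") + "/events",
        data=event.to_json().encode("utf-8"),
        headers={"Content-Type": "application/json"},
        method="POST",
    )
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            return json.loads(resp.read().decode("utf-8"))
    except urllib.error.HTTPError as exc:  # e.g. 409 duplicate
        return json.loads(exc.read().decode("utf-8"))
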