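"""HTTP front-end: identifier translation as tab-delimited plain text.

The service routes URL paths of the form ``/{organism}/{command}/{args...}``
to a mapper handle configured per organism, e.g.::

    GET /Human/search/ENSG00000122375

returns the free-search hits for that query against the mapper registered
under ``Human``, one ``identifier<TAB>data source full name`` row per line.
Commands:

* ``search/<query>``      — free-text search (attested route grammar);
* ``xrefs/<syscode>/<id>[?target=<syscode>]`` — identifier mapping
  (extension route, consistent with the same URL scheme);
* ``properties``          — capability and provenance introspection
  (extension route).

Responses are deterministic: rows are sorted, the content type is
``text/plain; charset=utf-8``, lines are joined with ``\\n`` and there is no
trailing newline. "No mapping found" is a valid answer — it returns 200
with an empty body; 404 is reserved for an unknown organism.

The application is a plain WSGI callable, so it can be served by any WSGI
server (the bundled CLI uses ``wsgiref``) and exercised in-process without
sockets via :func:`wsgi_request`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional
from urllib.parse import parse_qs, unquote
from wsgiref.simple_server import make_server

import yaml

from .core import DataSourceRegistry, Xref, default_registry
from .errors import UnknownDataSourceError, XrefBridgeError
from .mapper import IDMapper, connect
from .stack import StackMapper, stack

DEFAULT_RESULT_LIMIT = 100


@dataclass
class ServiceConfig:
    """Routing table for the service: organism name → mapper handle."""

    organisms: dict[str, IDMapper]
    host: str = "127.0.0.1"
    port: int = 8183
    result_limit: int = DEFAULT_RESULT_LIMIT

    def __post_init__(self) -> None:
        for name in self.organisms:
            if not name:
                raise XrefBridgeError("organism names must be non-empty")


def _rows(xrefs: Iterable[Xref]) -> str:
    lines = sorted(
        f"{x.identifier}\t{x.datasource.full_name}" for x in xrefs
    )
    # sort key (full_name, identifier) for a stable, human-scannable body
    lines = sorted(lines, key=lambda line: (line.split("\t")[1], line.split("\t")[0]))
    return "\n".join(lines)


def create_app(config: ServiceConfig, registry: Optional[DataSourceRegistry] = None):
    """Build the WSGI application for a service configuration."""
    if registry is None:
        registry = default_registry()

    def respond(start_response, status: str, body: str):
        data = body.encode("utf-8")
        start_response(
            status,
            [
                ("Content-Type", "text/plain; charset=utf-8"),
                ("Content-Length", str(len(data))),
            ],
        )
        return [data]

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "")
        query_string = environ.get("QUERY_STRING", "")
        segments = [unquote(s) for s in path.strip("/").split("/")] if path.strip("/") else []
        if len(segments) < 2:
            return respond(start_response, "400 Bad Request", "expected /{organism}/{command}/...")
        organism, command, *args = segments
        mapper = config.organisms.get(organism)
        if mapper is None:
            known = ", ".join(sorted(config.organisms)) or "none"
            return respond(
                start_response,
                "404 Not Found",
                f"unknown organism {organism!r}; configured organisms: {known}",
            )

        try:
            if command == "search":
                if len(args) != 1 or not args[0]:
                    return respond(start_response, "400 Bad Request", "empty search query")
                hits = mapper.free_search(args[0], limit=config.result_limit)
                return respond(start_response, "200 OK", _rows(hits))

            if command == "xrefs":
                if len(args) != 2 or not args[0] or not args[1]:
                    return respond(
                        start_response, "400 Bad Request", "expected xrefs/{syscode}/{identifier}"
                    )
                syscode, identifier = args
                try:
                    source = registry.by_syscode(syscode)
                except UnknownDataSourceError as exc:
                    return respond(start_response, "400 Bad Request", str(exc))
                targets: frozenset = frozenset()
                params = parse_qs(query_string)
                if "target" in params:
                    try:
                        targets = frozenset(
                            registry.by_syscode(c) for c in params["target"]
                        )
                    except UnknownDataSourceError as exc:
                        return respond(start_response, "400 Bad Request", str(exc))
                hits = mapper.map_id(Xref(source, identifier), targets)
                return respond(start_response, "200 OK", _rows(hits))

            if command == "properties":
                caps = mapper.capabilities()
                lines = []
                for ds in sorted(caps.source_datasources, key=lambda d: d.syscode):
                    lines.append(f"SupportedSource\t{ds.syscode}")
                for ds in sorted(caps.target_datasources, key=lambda d: d.syscode):
                    lines.append(f"SupportedTarget\t{ds.syscode}")
                lines.append(f"SupportsFreeSearch\t{str(caps.supports_free_search).lower()}")
                if isinstance(mapper, StackMapper):
                    lines.append(f"Transitive\t{str(mapper.transitive).lower()}")
                    lines.append(f"MaxDegree\t{mapper.max_degree}")
                dbinfo = getattr(mapper, "dbinfo", None)
                if callable(dbinfo):
                    info = dbinfo()
                    lines.append(f"schema_version\t{info.schema_version}")
                    lines.append(f"species_name\t{info.species_name}")
                    lines.append(f"build_timestamp\t{info.build_timestamp}")
                    lines.append(f"provenance\t{info.provenance}")
                return respond(start_response, "200 OK", "\n".join(lines))
        except XrefBridgeError as exc:
            return respond(start_response, "400 Bad Request", str(exc))

        return respond(
            start_response,
            "400 Bad Request",
            f"unknown command {command!r}; expected search, xrefs or properties",
        )

    return app


def wsgi_request(app: Callable, path: str) -> tuple[int, str]:
    """Invoke a WSGI app in-process for one GET request.

    Returns ``(status_code, body)``. Used by the test-suite and handy for
    smoke-checking a configuration without binding a socket.
    """
    raw_path, _, query = path.partition("?")
    environ = {
        "REQUEST_METHOD": "GET",
        "PATH_INFO": raw_path,
        "QUERY_STRING": query,
        "SERVER_NAME": "localhost",
        "SERVER_PORT": "80",
        "wsgi.url_scheme": "http",
    }
    captured: dict = {}

    def start_response(status, headers):
        captured["status"] = status
        captured["headers"] = headers

    chunks = app(environ, start_response)
    body = b"".join(chunks).decode("utf-8")
    return int(captured["status"].split()[0]), body


def load_service_config(
    path: str | Path, registry: Optional[DataSourceRegistry] = None
) -> ServiceConfig:
    """Load a YAML service configuration.

    Schema::

        host: 127.0.0.1       # optional
        port: 8183            # optional
        result_limit: 100     # optional
        organisms:
          Human: "idmapper-db:/data/human.xdb"
          HumanFull:
            connect:
              - "idmapper-db:/data/human.xdb"
              - "idmapper-db:/data/metabolites.xdb"
            transitive: true
            max_degree: 2
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    organisms: dict[str, IDMapper] = {}
    for name, entry in (raw.get("organisms") or {}).items():
        if isinstance(entry, str):
            organisms[name] = connect(entry, registry)
        else:
            members = [connect(cs, registry) for cs in entry["connect"]]
            if len(members) == 1 and not entry.get("transitive"):
                organisms[name] = members[0]
            else:
                organisms[name] = stack(
                    members,
                    transitive=bool(entry.get("transitive", False)),
                    max_degree=int(entry.get("max_degree", 2)),
                )
    return ServiceConfig(
        organisms=organisms,
        host=raw.get("host", "127.0.0.1"),
        port=int(raw.get("port", 8183)),
        result_limit=int(raw.get("result_limit", DEFAULT_RESULT_LIMIT)),
    )


def serve(config: ServiceConfig, registry: Optional[DataSourceRegistry] = None) -> None:
    """Run the service on ``config.host:config.port`` until interrupted."""
    app = create_app(config, registry)
    with make_server(config.host, config.port, app) as httpd:
        httpd.serve_forever()
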