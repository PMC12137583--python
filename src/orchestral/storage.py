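"""Persist workflow documents in an embedded SQLite store.

Documents are stored as canonical JSON text under a unique human-readable
name; a ``protected`` flag guards curated workflows against overwrite and
deletion.  The store never contains an invalid document: every save re-parses
through the public schema first.
"""

from __future__ import annotations

import datetime as _dt
import sqlite3
from dataclasses import dataclass

from .errors import (
    ProtectedWorkflowError,
    WorkflowExistsError,
    WorkflowNotFoundError,
)
from .workflow import WorkflowScript, from_document, to_document

SCHEMA_STAMP = 1


@dataclass(frozen=True)
class StoredWorkflow:
    name: str
    document: str
    protected: bool
    created_at: str
    updated_at: str


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat()


class WorkflowStore:
    """Single-file embedded store; pass ``":memory:"`` for an ephemeral one."""

    def __init__(self, path=":memory:"):
        self._conn = sqlite3.connect(str(path))
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT)")
        self._conn.execute(
            "INSERT OR IGNORE INTO meta VALUES ('schema_version', ?)",
            (str(SCHEMA_STAMP),))
        self._conn.execute(
            """CREATE TABLE IF NOT EXISTS workflows (
                   id INTEGER PRIMARY KEY,
                   name TEXT UNIQUE NOT NULL,
                   document TEXT NOT NULL,
                   protected INTEGER NOT NULL DEFAULT 0,
                   created_at TEXT NOT NULL,
                   updated_at TEXT NOT NULL)""")
        self._conn.commit()

    def close(self):
        self._conn.close()

    # -- operations ---------------------------------------------------------

    def save_workflow(self, name: str, w: WorkflowScript,
                      overwrite: bool = False) -> StoredWorkflow:
        doc = to_document(w)
        from_document(doc)  # the store never holds an invalid document
        row = self._row(name)
        now = _now()
        if row is None:
            self._conn.execute(
                "INSERT INTO workflows (name, document, protected, created_at, "
                "updated_at) VALUES (?, ?, 0, ?, ?)", (name, doc, now, now))
        else:
            if not overwrite:
                raise WorkflowExistsError(
                    f"workflow {name!r} exists (pass overwrite=True to replace)")
            if row["protected"]:
                raise ProtectedWorkflowError(f"workflow {name!r} is protected")
            self._conn.execute(
                "UPDATE workflows SET document = ?, updated_at = ? WHERE name = ?",
                (doc, now, name))
        self._conn.commit()
        return self._stored(self._row(name))

    def load_workflow(self, name: str) -> WorkflowScript:
        row = self._row(name)
        if row is None:
            raise WorkflowNotFoundError(f"no workflow named {name!r}")
        return from_document(row["document"])

    def get_document(self, name: str) -> StoredWorkflow:
        row = self._row(name)
        if row is None:
            raise WorkflowNotFoundError(f"no workflow named {name!r}")
        return self._stored(row)

    def list_workflows(self) -> list[dict]:
        """Summaries ordered by last update, newest first."""
        cur = self._conn.execute(
            "SELECT name, protected, created_at, updated_at FROM workflows "
            "ORDER BY updated_at DESC, id DESC")
        return [
            {"name": r[0], "protected": bool(r[1]),
             "created_at": r[2], "updated_at": r[3]}
            for r in cur.fetchall()
        ]

    def delete_workflow(self, name: str) -> None:
        row = self._row(name)
        if row is None:
            raise WorkflowNotFoundError(f"no workflow named {name!r}")
        if row["protected"]:
            raise ProtectedWorkflowError(f"workflow {name!r} is protected")
        self._conn.execute("DELETE FROM workflows WHERE name = ?", (name,))
        self._conn.commit()

    def set_protected(self, name: str, flag: bool) -> None:
        row = self._row(name)
        if row is None:
            raise WorkflowNotFoundError(f"no workflow named {name!r}")
        self._conn.execute(
            "UPDATE workflows SET protected = ? WHERE name = ?",
            (1 if flag else 0, name))
        self._conn.commit()

    # -- helpers ------------------------------------------------------------

    def _row(self, name):
        cur = self._conn.execute(
            "SELECT name, document, protected, created_at, updated_at "
            "FROM workflows WHERE name = ?", (name,))
        r = cur.fetchone()
        if r is None:
            return None
        return {"name": r[0], "document": r[1], "protected": bool(r[2]),
                "created_at": r[3], "updated_at": r[4]}

    @staticmethod
    def _stored(row) -> StoredWorkflow:
        return StoredWorkflow(
            name=row["name"], document=row["document"], protected=row["protected"],
            created_at=row["created_at"], updated_at=row["updated_at"])
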