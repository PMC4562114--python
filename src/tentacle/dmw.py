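"""Dynamic master-worker job distribution.

A master process holds a FIFO queue of jobs. Workers register whenever they
come online, pull one job at a time, execute it, and report done or failed;
failed jobs are requeued up to a retry limit, after which they are abandoned.
The master exchanges only small control messages (register / job / done /
failed / status / shutdown) and is never involved in moving data or results:
workers fetch their inputs and write their outputs themselves.

Messaging is request-reply over a single master TCP socket using the standard
library's ``multiprocessing.connection`` primitives; one connection carries
one request and its reply.
"""

from __future__ import annotations

import logging
import os
import socket
import time
import traceback
from dataclasses import dataclass, field, replace
from multiprocessing.connection import AuthenticationError, Client, Listener
from typing import Any, Callable, Optional, Sequence, Union

logger = logging.getLogger(__name__)

AUTHKEY = b"tentacle-dmw"

#: Terminal job states.
TERMINAL = ("done", "abandoned")


@dataclass(slots=True)
class Job:
    """A unit of distributable work: paths to the job's files plus options."""

    job_id: str
    reads_path: str
    reference_path: str
    annotations_path: str
    output_path: str
    options: Any = None

    def __post_init__(self):
        for name in ("reads_path", "reference_path", "annotations_path"):
            if not getattr(self, name):
                raise ValueError(f"job {self.job_id!r}: {name} is empty")


@dataclass(slots=True)
class JobStatus:
    """Lifecycle state of one job inside the master."""

    job_id: str
    state: str = "queued"  # queued | running | done | failed | abandoned
    attempts: int = 0      # number of dispatches so far
    worker_id: Optional[str] = None
    error: Optional[str] = None


@dataclass
class RunSummary:
    """What master_serve returns: final per-job status plus the master log."""

    statuses: dict[str, JobStatus]
    log: list[str] = field(default_factory=list)

    @property
    def done(self) -> list[str]:
        return [j for j, s in self.statuses.items() if s.state == "done"]

    @property
    def abandoned(self) -> list[str]:
        return [j for j, s in self.statuses.items() if s.state == "abandoned"]


Endpoint = Union[str, tuple[str, int]]


def parse_endpoint(endpoint: Endpoint) -> tuple[str, int]:
    """Accept 'host:port' or a (host, port) tuple."""
    if isinstance(endpoint, tuple):
        return endpoint[0], int(endpoint[1])
    host, _, port = endpoint.rpartition(":")
    if not host or not port.isdigit():
        raise ValueError(f"endpoint {endpoint!r} is not host:port")
    return host, int(port)


def free_endpoint(host: str = "127.0.0.1") -> tuple[str, int]:
    """Pick an OS-assigned free TCP port on *host*."""
    with socket.socket() as s:
        s.bind((host, 0))
        return host, s.getsockname()[1]


class _Master:
    """Mutable master state; master_serve drives it."""

    def __init__(self, jobs: Sequence[Job], retry_limit: int,
                 heartbeat_timeout: float):
        ids = [j.job_id for j in jobs]
        if len(set(ids)) != len(ids):
            raise ValueError("job_ids must be unique within a run")
        self.jobs = {j.job_id: j for j in jobs}
        self.queue: list[str] = list(ids)
        self.statuses = {j: JobStatus(j) for j in ids}
        self.retry_limit = retry_limit
        self.heartbeat_timeout = heartbeat_timeout
        self.dispatch_time: dict[str, float] = {}
        self.last_seen: dict[str, float] = {}  # active workers
        self.log: list[str] = []

    def _log(self, msg: str) -> None:
        line = f"{time.strftime('%H:%M:%S')} {msg}"
        self.log.append(line)
        logger.info("master: %s", msg)

    # -- queue mechanics ----------------------------------------------------

    def all_terminal(self) -> bool:
        return all(s.state in TERMINAL for s in self.statuses.values())

    def _requeue_or_abandon(self, job_id: str, error: Optional[str]) -> None:
        status = self.statuses[job_id]
        status.worker_id = None
        status.error = error
        self.dispatch_time.pop(job_id, None)
        # attempts counts dispatches; the first try plus retry_limit reruns
        if status.attempts <= self.retry_limit:
            status.state = "queued"
            self.queue.append(job_id)
            self._log(f"job {job_id} requeued (attempt {status.attempts} "
                      f"failed: {error})")
        else:
            status.state = "abandoned"
            self._log(f"job {job_id} abandoned after {status.attempts} "
                      f"attempts: {error}")

    def _next_reply(self, worker_id: str) -> tuple:
        """Reply to a worker asking for work: a job, wait, or shutdown."""
        if self.queue:
            job_id = self.queue.pop(0)  # FIFO dispatch
            status = self.statuses[job_id]
            status.state = "running"
            status.worker_id = worker_id
            status.attempts += 1
            self.dispatch_time[job_id] = time.monotonic()
            self._log(f"job {job_id} -> worker {worker_id} "
                      f"(attempt {status.attempts})")
            return ("job", self.jobs[job_id])
        if self.all_terminal():
            self.last_seen.pop(worker_id, None)
            self._log(f"worker {worker_id} shut down")
            return ("shutdown", None)
        return ("wait", 0.1)

    # -- message handling ---------------------------------------------------

    def handle(self, msg: tuple) -> tuple:
        kind = msg[0]
        if kind == "status":
            return ("status", [replace(s) for s in self.statuses.values()])
        worker_id = msg[1]
        self.last_seen[worker_id] = time.monotonic()
        if kind == "register":
            return self._next_reply(worker_id)
        if kind in ("done", "failed"):
            job_id = msg[2]
            status = self.statuses.get(job_id)
            if (status is None or status.state != "running"
                    or status.worker_id != worker_id):
                # duplicate or stale report: exactly-once means we reject it
                self._log(f"ignored stale {kind} report for {job_id} "
                          f"from {worker_id}")
            elif kind == "done":
                status.state = "done"
                status.error = None
                self.dispatch_time.pop(job_id, None)
                self._log(f"job {job_id} done on worker {worker_id}")
            else:
                self._requeue_or_abandon(job_id, msg[3])
            return self._next_reply(worker_id)
        raise ValueError(f"unknown message kind {kind!r}")

    def reap_stale(self) -> None:
        """Requeue jobs whose worker went silent past the heartbeat timeout."""
        now = time.monotonic()
        for job_id, t0 in list(self.dispatch_time.items()):
            if now - t0 > self.heartbeat_timeout:
                status = self.statuses[job_id]
                self._log(f"worker {status.worker_id} silent on job {job_id} "
                          f"for {self.heartbeat_timeout:.0f}s; requeueing")
                self.last_seen.pop(status.worker_id, None)
                self._requeue_or_abandon(job_id, "worker heartbeat timeout")


def master_serve(jobs: Sequence[Job], endpoint: Endpoint,
                 retry_limit: int = 3, heartbeat_timeout: float = 60.0,
                 drain_timeout: float = 10.0,
                 poll_interval: float = 0.05) -> RunSummary:
    """Serve *jobs* to workers at *endpoint* until all are done or abandoned.

    Jobs are dispatched FIFO to whichever worker asks; a failure report
    requeues the job up to *retry_limit* reruns. After the last job reaches a
    terminal state the master keeps answering for up to *drain_timeout*
    seconds so idle workers receive their shutdown, then returns the
    :class:`RunSummary`. The master never touches job data files.
    """
    address = parse_endpoint(endpoint)
    master = _Master(jobs, retry_limit, heartbeat_timeout)
    try:
        listener = Listener(address, authkey=AUTHKEY)
    except OSError as exc:
        raise OSError(f"cannot bind master endpoint {address}: {exc}") from exc
    listener._listener._socket.settimeout(poll_interval)  # type: ignore[attr-defined]
    master._log(f"serving {len(jobs)} job(s) at {address[0]}:{address[1]} "
                f"(retry_limit={retry_limit})")
    drain_start = None
    try:
        while True:
            if master.all_terminal():
                now = time.monotonic()
                if drain_start is None:
                    drain_start = now
                if not master.last_seen or now - drain_start > drain_timeout:
                    break
            else:
                drain_start = None
            master.reap_stale()
            try:
                conn = listener.accept()
            except (socket.timeout, TimeoutError):
                continue
            except AuthenticationError:
                master._log("rejected connection: authentication failed")
                continue
            except OSError:
                continue
            try:
                if not conn.poll(2.0):
                    master._log("dropped silent connection")
                    continue
                msg = conn.recv()
                conn.send(master.handle(msg))
            except (EOFError, OSError, ValueError) as exc:
                master._log(f"protocol violation: {exc}")
            finally:
                conn.close()
    finally:
        listener.close()
    master._log(f"run complete: {sum(1 for s in master.statuses.values() if s.state == 'done')} done, "
                f"{sum(1 for s in master.statuses.values() if s.state == 'abandoned')} abandoned")
    return RunSummary(statuses=master.statuses, log=master.log)


def _request(address: tuple[str, int], msg: tuple,
             connect_retries: int = 40, retry_delay: float = 0.25,
             reply_timeout: float = 300.0) -> tuple:
    """One request-reply exchange with the master, with bounded reconnects."""
    last_exc: Optional[Exception] = None
    for _ in range(connect_retries):
        try:
            conn = Client(address, authkey=AUTHKEY)
        except (ConnectionRefusedError, ConnectionResetError, OSError,
                AuthenticationError, EOFError) as exc:
            last_exc = exc
            time.sleep(retry_delay)
            continue
        try:
            conn.send(msg)
            if not conn.poll(reply_timeout):
                raise ConnectionError("master did not reply in time")
            return conn.recv()
        except (EOFError, OSError) as exc:
            last_exc = exc
            time.sleep(retry_delay)
        finally:
            conn.close()
    raise ConnectionError(
        f"master at {address[0]}:{address[1]} unreachable: {last_exc}")


def worker_loop(endpoint: Endpoint, executor: Callable[[Job], Any],
                worker_id: Optional[str] = None,
                connect_retries: int = 40, retry_delay: float = 0.25) -> int:
    """Register with the master and process jobs until told to shut down.

    *executor* is called with each :class:`Job`; an exception becomes a
    failure report (with the traceback as the message) and the loop
    continues with the next job. Returns the number of jobs completed.
    The worker reads inputs and writes outputs itself; only control
    messages travel to the master.
    """
    address = parse_endpoint(endpoint)
    if worker_id is None:
        worker_id = f"{socket.gethostname()}-{os.getpid()}"
    completed = 0
    msg: tuple = ("register", worker_id)
    while True:
        reply = _request(address, msg, connect_retries, retry_delay)
        kind, payload = reply[0], reply[1]
        if kind == "shutdown":
            logger.info("worker %s: shutdown after %d job(s)",
                        worker_id, completed)
            return completed
        if kind == "wait":
            time.sleep(payload)
            msg = ("register", worker_id)
            continue
        if kind != "job":
            raise ConnectionError(f"unexpected master reply {kind!r}")
        job: Job = payload
        try:
            executor(job)
        except Exception as exc:  # noqa: BLE001 - any failure is reported
            err = f"{type(exc).__name__}: {exc}"
            logger.warning("worker %s: job %s failed: %s\n%s",
                           worker_id, job.job_id, err, traceback.format_exc())
            msg = ("failed", worker_id, job.job_id, err)
        else:
            completed += 1
            msg = ("done", worker_id, job.job_id)


def query_status(endpoint: Endpoint, connect_retries: int = 1,
                 retry_delay: float = 0.1) -> list[JobStatus]:
    """Read-only snapshot of every job's status from a running master."""
    address = parse_endpoint(endpoint)
    reply = _request(address, ("status",), connect_retries, retry_delay,
                     reply_timeout=10.0)
    if reply[0] != "status":
        raise ConnectionError(f"unexpected master reply {reply[0]!r}")
    return reply[1]
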