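"""Self-contained interactive HTML output for a :class:`~qhtsplot.scene.Scene3D`.

The emitted file embeds the scene as JSON plus a small vanilla-JS
orthographic canvas renderer: drag rotates, the mouse wheel zooms,
shift-drag (or right-drag) pans.  No external scripts or styles are
referenced, so the file works offline and archives cleanly.
"""

from __future__ import annotations

from .scene import Scene3D

_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>qHTS waterfall plot</title>
<style>
  html, body { margin: 0; height: 100%; overflow: hidden; background: __BG__; }
  #plot { width: 100vw; height: 100vh; display: block; cursor: grab; }
  #hint { position: fixed; left: 8px; bottom: 6px; font: 12px sans-serif;
          color: #888; user-select: none; }
</style>
</head>
<body>
<canvas id="plot"></canvas>
<div id="hint">drag: rotate &nbsp; wheel: zoom &nbsp; shift-drag: pan</div>
<script id="scene-data" type="application/json">__SCENE_JSON__</script>
<script>
"use strict";
const SCENE = JSON.parse(document.getElementById("scene-data").textContent);
const canvas = document.getElementById("plot");
const ctx = canvas.getContext("2d");
const cam = Object.assign({yaw: -1.1, pitch: 0.35, zoom: 1.0}, SCENE.camera);
let panX = 0, panY = 0;

const R = SCENE.ranges, A = SCENE.aspect_ratio;
const span = k => Math.max(R[k][1] - R[k][0], 1e-9);
// normalize each axis to [-0.5, 0.5] * aspect
const NX = v => ((v - R.x[0]) / span("x") - 0.5) * A[0];
const NY = v => ((v - R.y[0]) / span("y") - 0.5) * A[1];
const NZ = v => ((v - R.z[0]) / span("z") - 0.5) * A[2];

function project(nx, ny, nz, s) {
  const cy = Math.cos(cam.yaw), sy = Math.sin(cam.yaw);
  const cp = Math.cos(cam.pitch), sp = Math.sin(cam.pitch);
  const rx = cy * nx + sy * ny;
  const ry = -sy * nx + cy * ny;
  const rz = cp * nz - sp * ry;
  return [canvas.width / 2 + panX + rx * s, canvas.height / 2 + panY - rz * s];
}

function axisEdges() {
  // bounding-box edges of the normalized data cube
  const c = [[-0.5,-0.5,-0.5],[0.5,-0.5,-0.5],[0.5,0.5,-0.5],[-0.5,0.5,-0.5],
             [-0.5,-0.5,0.5],[0.5,-0.5,0.5],[0.5,0.5,0.5],[-0.5,0.5,0.5]]
            .map(p => [p[0]*A[0], p[1]*A[1], p[2]*A[2]]);
  const e = [[0,1],[1,2],[2,3],[3,0],[4,5],[5,6],[6,7],[7,4],[0,4],[1,5],[2,6],[3,7]];
  return {c: c, e: e};
}

function draw() {
  const w = canvas.width, h = canvas.height;
  ctx.fillStyle = SCENE.background_color || "white";
  ctx.fillRect(0, 0, w, h);
  const s = Math.min(w, h) * 0.55 * cam.zoom;

  const box = axisEdges();
  ctx.strokeStyle = "#bbb"; ctx.lineWidth = 1;
  ctx.beginPath();
  for (const [a, b] of box.e) {
    const p = project(...box.c[a], s), q = project(...box.c[b], s);
    ctx.moveTo(p[0], p[1]); ctx.lineTo(q[0], q[1]);
  }
  ctx.stroke();
  ctx.fillStyle = "#666"; ctx.font = "12px sans-serif";
  const lx = project(0, -0.55 * A[1], -0.55 * A[2], s);
  ctx.fillText(SCENE.axis_labels[0], lx[0], lx[1]);
  const ly = project(0.55 * A[0], 0, -0.55 * A[2], s);
  ctx.fillText(SCENE.axis_labels[1], ly[0], ly[1]);
  const lz = project(-0.55 * A[0], -0.55 * A[1], 0, s);
  ctx.fillText(SCENE.axis_labels[2], lz[0], lz[1]);

  for (const t of SCENE.traces) {
    const nx = NX(t.x);
    if (t.kind === "line") {
      ctx.strokeStyle = t.color; ctx.lineWidth = t.width || 1;
      ctx.beginPath();
      for (let i = 0; i < t.y.length; i++) {
        const p = project(nx, NY(t.y[i]), NZ(t.z[i]), s);
        if (i === 0) ctx.moveTo(p[0], p[1]); else ctx.lineTo(p[0], p[1]);
      }
      ctx.stroke();
    } else {
      ctx.fillStyle = t.color;
      const r = Math.max(t.size || 3, 1);
      for (let i = 0; i < t.y.length; i++) {
        const p = project(nx, NY(t.y[i]), NZ(t.z[i]), s);
        ctx.fillRect(p[0] - r / 2, p[1] - r / 2, r, r);
      }
    }
  }
}

function resize() {
  canvas.width = window.innerWidth;
  canvas.height = window.innerHeight;
  draw();
}
window.addEventListener("resize", resize);

let dragging = false, panning = false, lastX = 0, lastY = 0;
canvas.addEventListener("mousedown", ev => {
  dragging = true;
  panning = ev.shiftKey || ev.button === 2;
  lastX = ev.clientX; lastY = ev.clientY;
});
window.addEventListener("mouseup", () => { dragging = false; });
window.addEventListener("mousemove", ev => {
  if (!dragging) return;
  const dx = ev.clientX - lastX, dy = ev.clientY - lastY;
  lastX = ev.clientX; lastY = ev.clientY;
  if (panning) { panX += dx; panY += dy; }
  else {
    cam.yaw += dx * 0.01;
    cam.pitch = Math.max(-1.55, Math.min(1.55, cam.pitch + dy * 0.01));
  }
  requestAnimationFrame(draw);
});
canvas.addEventListener("wheel", ev => {
  ev.preventDefault();
  cam.zoom *= Math.exp(-ev.deltaY * 0.001);
  cam.zoom = Math.max(0.05, Math.min(50, cam.zoom));
  requestAnimationFrame(draw);
}, {passive: false});
canvas.addEventListener("contextmenu", ev => ev.preventDefault());

resize();
</script>
</body>
</html>
"""


def render_html(scene: Scene3D) -> str:
    """Serialize the scene into a standalone interactive HTML document."""
    payload = scene.to_json()
    # keep the JSON safe inside a <script> element
    payload = payload.replace("</", "<\\/")
    return (
        _TEMPLATE
        .replace("__BG__", scene.background_color)
        .replace("__SCENE_JSON__", payload)
    )
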