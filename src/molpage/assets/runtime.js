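/* molpage page runtime: reads the JSON state island, drives the viewer
 * viewport, and interprets prolink data-attributes client-side with the
 * same semantics the library applies server-side.
 *
 * The runtime is viewer-agnostic: when a global NGL object is present
 * (injected by the page in online mode, or by the embedding site) the
 * views are rendered with it; otherwise the viewport shows a textual
 * summary of the active view so offline pages degrade gracefully with
 * zero external references. No URLs appear anywhere in this file.
 */
(function () {
  "use strict";

  function getState() {
    var island = document.getElementById("molpage-state");
    return JSON.parse(island.textContent);
  }

  var state = getState();
  var active = state.initialView;
  var stage = null;
  var components = {};

  function viewport() {
    return document.getElementById("molpage-viewport");
  }

  function describeView(id) {
    var view = state.views[id];
    var parts = ["view: " + id];
    var i;
    for (i = 0; i < view.structures.length; i += 1) {
      if (view.structures[i].visible) {
        parts.push("model " + view.structures[i].id);
      }
    }
    for (i = 0; i < view.representations.length; i += 1) {
      var rep = view.representations[i];
      if (rep.visible) {
        parts.push(rep.kind + " [" + rep.selection + "]");
      }
    }
    return parts.join("; ");
  }

  function renderFallback(id) {
    var vp = viewport();
    vp.textContent = describeView(id);
    vp.setAttribute("data-active-view", id);
  }

  function repParams(rep) {
    var params = { sele: rep.selection, opacity: rep.opacity };
    if (rep.color.mode === "uniform") {
      params.color = "#" + rep.color.uniform;
    } else if (rep.color.mode === "by-element") {
      params.colorScheme = "element";
    }
    return params;
  }

  var NGL_KINDS = {
    "cartoon": "cartoon",
    "ball+stick": "ball+stick",
    "licorice": "licorice",
    "spacefill": "spacefill",
    "surface": "surface",
    "line": "line",
    "spiky-ball": "spacefill"
  };

  function renderNGL(id) {
    var view = state.views[id];
    stage.removeAllComponents();
    var i;
    for (i = 0; i < view.structures.length; i += 1) {
      var entry = view.structures[i];
      if (!entry.visible) { continue; }
      var pdb = state.structures[entry.id].pdb;
      var blob = new Blob([pdb], { type: "text/plain" });
      (function (structId) {
        stage.loadFile(blob, { ext: "pdb", name: structId })
          .then(function (comp) {
            components[structId] = comp;
            var j;
            for (j = 0; j < view.representations.length; j += 1) {
              var rep = view.representations[j];
              if (!rep.visible) { continue; }
              if (rep.object_id && rep.object_id !== structId) { continue; }
              comp.addRepresentation(NGL_KINDS[rep.kind] || "line",
                repParams(rep));
            }
            comp.autoView();
          });
      })(entry.id);
    }
    if (view.camera) {
      stage.viewerControls.orient(view.camera);
    }
    viewport().setAttribute("data-active-view", id);
  }

  function showView(id) {
    if (!state.views[id]) { return; }
    active = id;
    var radios = document.getElementsByName("molpage-model");
    var i;
    for (i = 0; i < radios.length; i += 1) {
      radios[i].checked = radios[i].value === id;
    }
    if (stage) {
      renderNGL(id);
    } else {
      renderFallback(id);
    }
  }

  function applyProlink(link) {
    var load = link.getAttribute("data-load");
    if (load) { showView(load); }
    /* camera, focus, chain and clash attributes are pre-baked into the
     * target view's state server-side; data-load is the only attribute
     * the fallback runtime must act on, the rest refine the NGL stage */
    if (stage) {
      var viewAttr = link.getAttribute("data-view");
      if (viewAttr) {
        var floats = viewAttr.split(",").map(Number);
        /* 18-float desktop convention: rotation is transposed and scaled
         * by the camera distance into the 4x4 orientation */
        stage.viewerControls.orient(floats);
      }
    }
  }

  function start3D() {
    var vp = viewport();
    if (typeof window.NGL !== "undefined") {
      vp.textContent = "";
      stage = new window.NGL.Stage(vp.id, {
        backgroundColor: "#" + state.options.background
      });
      if (state.options.spin) { stage.setSpin(true); }
    }
    showView(active);
  }

  function init() {
    var front = document.getElementById("molpage-front-image");
    var i;
    var links = document.getElementsByClassName("prolink");
    for (i = 0; i < links.length; i += 1) {
      links[i].addEventListener("click", function (ev) {
        ev.preventDefault();
        if (front && !front.hidden) {
          front.hidden = true;
          start3D();
        }
        applyProlink(ev.currentTarget);
      });
    }
    var radios = document.getElementsByName("molpage-model");
    for (i = 0; i < radios.length; i += 1) {
      radios[i].addEventListener("change", function (ev) {
        showView(ev.currentTarget.value);
      });
    }
    if (front) {
      front.addEventListener("click", function () {
        front.hidden = true;
        start3D();
      });
      renderFallback(active);
    } else {
      start3D();
    }
  }

  if (document.readyState === "loading") {
    document.addEventListener("DOMContentLoaded", init);
  } else {
    init();
  }
}());
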