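#!/usr/bin/env Rscript
# Convert an hclust-style clustering (merge, height, order, labels) into the
# dendroselect JSON interchange schema, mirroring the Python writer's
# structure (schema_version, labels, linkage, node_names, orientation).
#
# Usage as a script (fixture generator):
#   Rscript r/get_json.R SEED N OUTDIR
# writes OUTDIR/r_tree.json (interchange JSON of an average-linkage hclust of
# N points with seeded uniform coordinates) and OUTDIR/r_cophenetic.csv (the
# cophenetic distance matrix of the same clustering, leaf-id order).

suppressMessages(library(jsonlite))

# signed 1-based hclust encoding -> condensed 0-based rows (a, b, height,
# count) with a < b; leaf -k maps to id k-1, merge row j to id n+j-1
condensed_rows <- function(hc) {
  n <- length(hc$order)
  counts <- c(rep(1L, n), rep(0L, n - 1))
  rows <- matrix(0, n - 1, 4)
  for (j in seq_len(n - 1)) {
    ids <- vapply(hc$merge[j, ], function(v) {
      if (v < 0) -v - 1 else n + v - 1
    }, numeric(1))
    ids <- sort(ids)
    cnt <- counts[ids[1] + 1] + counts[ids[2] + 1]
    counts[n + j] <- cnt
    rows[j, ] <- c(ids[1], ids[2], hc$height[j], cnt)
  }
  rows
}

get_json <- function(hc, labels, path, orientation = "horizontal") {
  if (is.null(labels)) stop("labels are required")
  n <- length(hc$order)
  if (length(labels) != n) stop("labels length must equal the leaf count")
  rows <- condensed_rows(hc)
  linkage <- lapply(seq_len(nrow(rows)), function(i) {
    list(rows[i, 1], rows[i, 2], rows[i, 3], rows[i, 4])
  })
  obj <- list(
    schema_version = "1.0",
    labels = as.list(as.character(labels)),
    linkage = linkage,
    node_names = setNames(list(), character(0)),
    orientation = orientation
  )
  writeLines(toJSON(obj, auto_unbox = TRUE, digits = NA), path)
  invisible(path)
}

args <- commandArgs(trailingOnly = TRUE)
if (length(args) == 3) {
  seed <- as.integer(args[1])
  n <- as.integer(args[2])
  outdir <- args[3]
  dir.create(outdir, showWarnings = FALSE, recursive = TRUE)
  set.seed(seed)
  x <- matrix(runif(n * 5), nrow = n)
  labels <- sprintf("L%02d", seq_len(n) - 1)
  hc <- hclust(dist(x), method = "average")
  get_json(hc, labels, file.path(outdir, "r_tree.json"))
  coph <- as.matrix(cophenetic(hc))
  write.table(coph, file.path(outdir, "r_cophenetic.csv"),
              sep = ",", row.names = FALSE, col.names = FALSE)
}
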