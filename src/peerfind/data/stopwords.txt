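# Default English stop-word list: one token per line, UTF-8.
# Function words and near-content-free fillers common in scientific abstracts.
a
about
above
after
again
against
all
almost
also
although
am
among
an
and
any
are
as
at
be
because
been
before
being
below
between
both
but
by
can
cannot
could
did
do
does
doing
done
down
during
each
either
else
few
for
from
further
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
however
i
if
in
into
is
it
its
itself
just
may
me
might
more
most
much
must
my
myself
neither
no
nor
not
of
off
often
on
once
only
onto
or
other
our
ours
ourselves
out
over
own
per
rather
same
she
should
since
so
some
such
than
that
the
their
theirs
them
themselves
then
there
therefore
these
they
this
those
through
thus
to
too
under
until
up
upon
us
very
via
was
we
were
what
when
where
whereas
whether
which
while
who
whom
whose
why
will
with
within
without
would
yet
you
your
yours
yourself
yourselves
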