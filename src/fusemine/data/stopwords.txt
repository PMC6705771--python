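a
about
above
after
again
against
all
also
am
an
and
another
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
could
did
do
does
down
during
each
etc
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
him
his
how
i
if
in
into
is
it
its
just
least
less
may
me
might
more
most
much
must
my
no
nor
not
of
off
on
once
only
or
other
our
out
over
own
per
same
shall
she
should
so
some
such
than
that
the
their
them
then
there
these
they
this
those
through
thus
to
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
which
while
who
whom
whose
will
with
within
without
would
you
your
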